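"""Dimensionality reduction (PCA, PLS) and class-separability diagnostics.

Both reductions use mean-centering only — spectra enter already
L2-normalized, so no unit-variance autoscaling is applied. Component signs
are fixed deterministically (largest-magnitude loading element made
positive) so scores, plots and tests are reproducible across runs and
library versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

__all__ = [
    "LatentModel",
    "pca_fit",
    "components_for_variance",
    "pls_fit",
    "fisher_ratio",
    "FisherResult",
]


@dataclass
class LatentModel:
    """A fitted PCA or PLS reduction.

    ``loadings`` has shape (n_points, n_components); PCA loadings are
    orthonormal. ``explained_variance_fraction`` is per-component and only
    populated for PCA. ``transform`` projects new spectra after removing
    the training mean.
    """

    kind: str
    n_components: int
    loadings: np.ndarray
    scores: np.ndarray
    center: np.ndarray
    explained_variance_fraction: np.ndarray | None = None
    _sk_model: object | None = None

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if self.kind == "PCA":
            return (matrix - self.center) @ self.loadings
        # PLS X-scores use the rotation matrix, not the loadings
        return (matrix - self.center) @ self._rotations

    @property
    def _rotations(self) -> np.ndarray:
        return self.__dict__["_rotations_"]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray, extra: np.ndarray | None = None):
    """Flip each component so its largest-magnitude loading entry is positive."""
    flips = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            flips[j] = -1.0
    loadings = loadings * flips
    scores = scores * flips
    if extra is not None:
        extra = extra * flips
    return loadings, scores, extra


def pca_fit(matrix: np.ndarray, n_components: int) -> LatentModel:
    """Mean-centered PCA via full SVD with a deterministic sign convention."""
    matrix = np.asarray(matrix, dtype=float)
    n_samples, n_points = matrix.shape
    max_rank = min(n_samples - 1, n_points)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components={n_components} must be in [1, {max_rank}] for a "
            f"{n_samples}x{n_points} matrix"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    loadings = pca.components_.T
    loadings, scores, _ = _fix_signs(loadings, scores)
    total_var = np.var(matrix - matrix.mean(axis=0), axis=0, ddof=1).sum()
    if total_var == 0:
        frac = np.zeros(n_components)
    else:
        frac = pca.explained_variance_ / total_var
    return LatentModel(
        kind="PCA",
        n_components=n_components,
        loadings=loadings,
        scores=scores,
        center=pca.mean_,
        explained_variance_fraction=frac,
    )


def components_for_variance(model: LatentModel, threshold: float) -> int:
    """Smallest number of leading PCs whose cumulative variance >= threshold."""
    if model.kind != "PCA" or model.explained_variance_fraction is None:
        raise ValueError("components_for_variance requires a PCA model")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(model.explained_variance_fraction)
    idx = np.searchsorted(cum, threshold - 1e-12)
    if idx >= len(cum):
        return len(cum)
    return int(idx) + 1


def pls_fit(matrix: np.ndarray, labels: np.ndarray, n_components: int) -> LatentModel:
    """Single-response PLS on 0/1 labels (NIPALS deflation, centering only)."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("PLS requires both classes present")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(matrix, labels)
    loadings = pls.x_loadings_
    scores = pls.x_scores_
    rotations = pls.x_rotations_
    loadings, scores, rotations = _fix_signs(loadings, scores, rotations)
    model = LatentModel(
        kind="PLS",
        n_components=n_components,
        loadings=loadings,
        scores=scores,
        center=matrix.mean(axis=0),
        _sk_model=pls,
    )
    model.__dict__["_rotations_"] = rotations
    return model


@dataclass
class FisherResult:
    value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def fisher_ratio(scores_axis: np.ndarray, labels: np.ndarray) -> FisherResult:
    """Two-class separability along one score axis.

    (mu0 - mu1)^2 / (var0 + var1) with per-class sample variances. A zero
    pooled variance yields +inf flagged degenerate.
    """
    scores_axis = np.asarray(scores_axis, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("fisher_ratio requires exactly two classes present")
    a = scores_axis[labels == classes[0]]
    b = scores_axis[labels == classes[1]]
    var_a = a.var(ddof=1) if len(a) > 1 else 0.0
    var_b = b.var(ddof=1) if len(b) > 1 else 0.0
    num = (a.mean() - b.mean()) ** 2
    denom = var_a + var_b
    if denom == 0.0:
        return FisherResult(value=np.inf if num > 0 else 0.0, degenerate=True)
    return FisherResult(value=float(num / denom))
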