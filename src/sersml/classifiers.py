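"""The four classifier families: LDA, QDA, SVM and random forest.

LDA and QDA are shrunk-covariance Gaussian discriminants: the (pooled or
per-class) covariance is blended toward a scaled identity,

    Sigma(r) = (1 - r) * Sigma + r * (tr Sigma / d) * I,   r in [0, 1),

which keeps the estimator well-conditioned on few samples. SVM and RF
delegate to scikit-learn solvers behind this module's interface; RF feature
importance is the impurity-decrease (Gini) importance normalized to sum
to one. All fits are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = ["ClassifierSpec", "FittedModel", "fit", "predict", "feature_importance"]

_FAMILIES = ("LDA", "QDA", "SVM", "RF")
_KERNELS = ("linear", "poly3", "rbf")
_MAX_FEATURES = ("log2", "sqrt", "all")


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameter bundle for one classifier family.

    Only the fields relevant to ``family`` may be set; the rest stay None.
    """

    family: str
    kernel: Optional[str] = None          # SVM
    C: Optional[float] = None             # SVM cost
    gamma: Optional[float] = None         # nonlinear SVM
    reg: Optional[float] = None           # LDA/QDA shrinkage
    n_trees: Optional[int] = None         # RF
    min_samples_split: Optional[int] = None
    min_samples_leaf: Optional[int] = None
    max_features: Optional[str] = None    # RF: log2 | sqrt | all
    max_depth: Optional[int] = None       # RF; None = unlimited

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("LDA", "QDA"):
            if self.reg is None or not (0.0 <= self.reg < 1.0):
                raise ValueError(f"{self.family} requires reg in [0, 1)")
            self._forbid("kernel", "C", "gamma", "n_trees", "min_samples_split",
                         "min_samples_leaf", "max_features", "max_depth")
        elif self.family == "SVM":
            if self.kernel not in _KERNELS:
                raise ValueError(f"SVM kernel must be one of {_KERNELS}")
            if self.C is None or self.C < 0:
                raise ValueError("SVM requires C >= 0")
            if self.kernel != "linear" and (self.gamma is None or self.gamma <= 0):
                raise ValueError("nonlinear SVM requires gamma > 0")
            if self.kernel == "linear" and self.gamma is not None:
                raise ValueError("linear SVM takes no gamma")
            self._forbid("reg", "n_trees", "min_samples_split",
                         "min_samples_leaf", "max_features", "max_depth")
        else:  # RF
            if self.n_trees is None or self.n_trees < 1:
                raise ValueError("RF requires n_trees >= 1")
            if self.min_samples_split is None or self.min_samples_split < 2:
                raise ValueError("RF requires min_samples_split >= 2")
            if self.min_samples_leaf is None or self.min_samples_leaf < 1:
                raise ValueError("RF requires min_samples_leaf >= 1")
            if self.max_features not in _MAX_FEATURES:
                raise ValueError(f"RF max_features must be one of {_MAX_FEATURES}")
            self._forbid("kernel", "C", "gamma", "reg")

    def _forbid(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is not None:
                raise ValueError(f"{self.family} does not take {name!r}")


@dataclass
class FittedModel:
    spec: ClassifierSpec
    n_features: int
    classes: np.ndarray
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def feature_importance_(self) -> np.ndarray | None:
        return self._state.get("importance")


def _shrunk_cov(cov: np.ndarray, r: float) -> np.ndarray:
    d = cov.shape[0]
    mu = np.trace(cov) / d
    return (1.0 - r) * cov + r * mu * np.eye(d)


def _fit_gaussian(spec: ClassifierSpec, x: np.ndarray, y: np.ndarray) -> dict:
    classes = np.unique(y)
    means = {c: x[y == c].mean(axis=0) for c in classes}
    priors = {c: float(np.mean(y == c)) for c in classes}
    d = x.shape[1]
    if spec.family == "LDA":
        pooled = np.zeros((d, d))
        for c in classes:
            xc = x[y == c] - means[c]
            pooled += xc.T @ xc
        pooled /= len(x) - len(classes)
        cov = _shrunk_cov(pooled, spec.reg)
        covs = {c: cov for c in classes}
    else:
        covs = {}
        for c in classes:
            xc = x[y == c] - means[c]
            if len(xc) < 2:
                raise ValueError(f"QDA needs >= 2 samples in class {c}")
            covs[c] = _shrunk_cov(xc.T @ xc / (len(xc) - 1), spec.reg)
    state = {"means": means, "priors": priors, "covs": covs}
    # precompute inverses and log-determinants; singular covariance -> error
    state["inv"] = {}
    state["logdet"] = {}
    for c in classes:
        sign, logdet = np.linalg.slogdet(covs[c])
        if sign <= 0:
            raise ValueError(
                f"{spec.family} covariance for class {c} is singular; increase reg"
            )
        state["inv"][c] = np.linalg.inv(covs[c])
        state["logdet"][c] = logdet
    return state


def _gaussian_scores(state: dict, x: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.empty((len(x), len(classes)))
    for j, c in enumerate(classes):
        diff = x - state["means"][c]
        maha = np.einsum("ij,jk,ik->i", diff, state["inv"][c], diff)
        out[:, j] = -0.5 * (maha + state["logdet"][c]) + np.log(state["priors"][c])
    return out


def fit(spec: ClassifierSpec, matrix: np.ndarray, labels: np.ndarray, seed: int = 0) -> FittedModel:
    """Fit one classifier; deterministic given ``seed``."""
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("matrix must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")

    model = FittedModel(spec=spec, n_features=x.shape[1], classes=classes)
    if spec.family in ("LDA", "QDA"):
        model._state.update(_fit_gaussian(spec, x, y))
    elif spec.family == "SVM":
        if spec.C <= 0:
            raise ValueError("SVM solver requires C > 0 (C=0 is a degenerate grid point)")
        kwargs = dict(C=spec.C, random_state=seed)
        if spec.kernel == "linear":
            clf = SVC(kernel="linear", **kwargs)
        elif spec.kernel == "poly3":
            clf = SVC(kernel="poly", degree=3, gamma=spec.gamma, **kwargs)
        else:
            clf = SVC(kernel="rbf", gamma=spec.gamma, **kwargs)
        clf.fit(x, y)
        model._state["sk"] = clf
    else:
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            min_samples_split=spec.min_samples_split,
            min_samples_leaf=spec.min_samples_leaf,
            max_features=None if spec.max_features == "all" else spec.max_features,
            max_depth=spec.max_depth,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(x, y)
        model._state["sk"] = clf
        model._state["importance"] = clf.feature_importances_
    return model


def predict(model: FittedModel, matrix: np.ndarray) -> np.ndarray:
    """Predict 0/1 labels; RF uses majority vote over trees with ties -> class 0."""
    x = np.asarray(matrix, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=int)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[1] if x.ndim == 2 else '1-D'}"
        )
    spec = model.spec
    if spec.family in ("LDA", "QDA"):
        scores = _gaussian_scores(model._state, x, model.classes)
        return model.classes[np.argmax(scores, axis=1)]
    if spec.family == "SVM":
        return model._state["sk"].predict(x).astype(int)
    # RF: explicit majority vote across trees; ties resolve to class 0
    votes1 = rf_tree_predictions(model, x).sum(axis=0)
    n = model.spec.n_trees
    return (2 * votes1 > n).astype(int)


def rf_tree_predictions(model: FittedModel, matrix: np.ndarray) -> np.ndarray:
    """Per-tree 0/1 predictions of an RF model, shape (n_trees, n_samples).

    The first n rows are exactly the predictions of the n-tree forest grown
    from the same seed, which lets a hyperparameter search share tree fits
    across the forest-size axis.
    """
    if model.spec.family != "RF":
        raise TypeError("rf_tree_predictions is only defined for RF models")
    x = np.asarray(matrix, dtype=float)
    clf = model._state["sk"]
    return np.array([t.predict(x) for t in clf.estimators_], dtype=int)


def decision_scores(model: FittedModel, matrix: np.ndarray) -> np.ndarray:
    """Continuous score for class 1, for ROC analysis."""
    x = np.asarray(matrix, dtype=float)
    spec = model.spec
    if spec.family in ("LDA", "QDA"):
        scores = _gaussian_scores(model._state, x, model.classes)
        j1 = int(np.where(model.classes == 1)[0][0])
        j0 = int(np.where(model.classes == 0)[0][0])
        return scores[:, j1] - scores[:, j0]
    if spec.family == "SVM":
        return model._state["sk"].decision_function(x)
    clf = model._state["sk"]
    proba = clf.predict_proba(x)
    j1 = int(np.where(clf.classes_ == 1)[0][0])
    return proba[:, j1]


def feature_importance(model: FittedModel) -> np.ndarray:
    """Mean-decrease-in-impurity importances of an RF model, summing to 1.

    A forest that never split returns all zeros (normalization skipped).
    """
    if model.spec.family != "RF":
        raise TypeError("feature_importance is only defined for RF models")
    imp = model._state["importance"]
    total = imp.sum()
    if total == 0:
        return np.zeros_like(imp)
    return imp / total
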