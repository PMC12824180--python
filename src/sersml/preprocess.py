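"""Spectral preprocessing chain and replicate-variability statistics.

The chain, applied in this fixed order to every spectrum:

1. crop to the analysis window (default 550-1800 cm^-1),
2. subtract the mean blank-substrate reference from the raw signal,
3. asymmetric-least-squares (ALS) baseline estimation and subtraction
   (lambda = 1e4, p = 0.001, 10 reweighting iterations) with a
   non-negativity clamp,
4. L2 vector normalization to unit Euclidean length.

ALS follows the Whittaker-smoother construction: minimize
sum_i w_i (y_i - z_i)^2 + lambda * sum (Delta^2 z)^2 with asymmetric
weights w_i = p where y_i > z_i (points above the baseline, presumed peaks)
and 1 - p below, re-estimated each iteration. The second-difference
penalty leaves straight lines invariant, so slowly varying backgrounds are
captured while narrow bands are left to the clamped residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .io import RamanSpectrum, SpectralDataset

__all__ = [
    "PreprocessParams",
    "SubstrateReference",
    "crop",
    "subtract_reference",
    "als_baseline",
    "baseline_correct",
    "l2_normalize",
    "preprocess_pipeline",
    "cv_statistics",
    "signal_ratio",
    "build_reference",
]


@dataclass
class PreprocessParams:
    crop_lo: float = 550.0
    crop_hi: float = 1800.0
    als_lambda: float = 1e4
    als_p: float = 0.001
    als_iterations: int = 10

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if not (0.0 < self.als_p < 1.0):
            raise ValueError("als_p must lie in (0, 1)")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be positive")
        if self.als_iterations < 1:
            raise ValueError("als_iterations must be >= 1")


@dataclass
class SubstrateReference:
    """Mean blank-strip spectrum used for substrate subtraction."""

    axis: np.ndarray
    mean_intensity: np.ndarray
    n_strips: int = 1

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if len(self.axis) != len(self.mean_intensity):
            raise ValueError("axis and mean_intensity must have equal length")
        if self.n_strips < 1:
            raise ValueError("n_strips must be >= 1")


def build_reference(spectra: list[RamanSpectrum]) -> SubstrateReference:
    """Pointwise mean over blank-strip spectra, on the raw measured signal."""
    if not spectra:
        raise ValueError("need at least one substrate spectrum")
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if len(s) != len(axis) or not np.allclose(s.wavenumbers, axis):
            raise ValueError("substrate spectra must share a common axis")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return SubstrateReference(axis=axis, mean_intensity=mean, n_strips=len(spectra))


def crop(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Keep exactly the points with lo <= wavenumber <= hi."""
    if lo >= hi:
        raise ValueError(f"crop bounds inverted: lo={lo} >= hi={hi}")
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"crop({lo}, {hi}) leaves no points")
    return RamanSpectrum(
        spectrum.wavenumbers[mask], spectrum.intensities[mask], dict(spectrum.meta)
    )


def subtract_reference(spectrum: RamanSpectrum, ref: SubstrateReference) -> RamanSpectrum:
    """Pointwise raw-signal difference; may be negative at this stage.

    Non-negativity is enforced only after baseline correction.
    """
    if len(spectrum) != len(ref.axis) or not np.allclose(spectrum.wavenumbers, ref.axis):
        raise ValueError("spectrum and substrate reference are on different axes")
    return RamanSpectrum(
        spectrum.wavenumbers,
        spectrum.intensities - ref.mean_intensity,
        dict(spectrum.meta),
    )


def als_baseline(y: np.ndarray, lam: float = 1e4, p: float = 0.001, n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline of a 1-D intensity vector.

    Solves (W + lam * D2'D2) z = W y with D2 the natural (unpadded)
    second-difference operator, iterating the asymmetric weight update
    w_i = p if y_i > z_i else 1 - p for ``n_iter`` rounds.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("als_baseline needs a 1-D vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("als_baseline input contains non-finite values")
    n = len(y)
    d2 = sparse.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (d2.T @ d2)).tocsc()
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = sparse.diags_array(w, offsets=0, shape=(n, n), format="csc")
        z = spsolve(wmat + penalty, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(spectrum: RamanSpectrum, params: PreprocessParams) -> RamanSpectrum:
    """Subtract the ALS baseline and clamp the result at zero."""
    base = als_baseline(
        spectrum.intensities, params.als_lambda, params.als_p, params.als_iterations
    )
    corrected = np.clip(spectrum.intensities - base, 0.0, None)
    return RamanSpectrum(spectrum.wavenumbers, corrected, dict(spectrum.meta))


def l2_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Scale to unit Euclidean length."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise ValueError("cannot L2-normalize an all-zero spectrum")
    return RamanSpectrum(
        spectrum.wavenumbers, spectrum.intensities / norm, dict(spectrum.meta)
    )


def preprocess_pipeline(
    dataset: SpectralDataset,
    ref: SubstrateReference | None,
    params: PreprocessParams | None = None,
) -> SpectralDataset:
    """Apply crop -> substrate subtraction -> ALS correction -> L2 norm rowwise."""
    params = params if params is not None else PreprocessParams()
    if dataset.n_samples == 0:
        return dataset
    rows = []
    axis_out = None
    for i in range(dataset.n_samples):
        spec = RamanSpectrum(dataset.axis, dataset.matrix[i])
        spec = crop(spec, params.crop_lo, params.crop_hi)
        if ref is not None:
            ref_c = SubstrateReference(
                *_crop_ref(ref, params.crop_lo, params.crop_hi), ref.n_strips
            )
            spec = subtract_reference(spec, ref_c)
        spec = baseline_correct(spec, params)
        spec = l2_normalize(spec)
        rows.append(spec.intensities)
        axis_out = spec.wavenumbers
    return SpectralDataset(
        axis=axis_out,
        matrix=np.vstack(rows),
        labels=dataset.labels,
        patient_ids=dataset.patient_ids,
    )


def _crop_ref(ref: SubstrateReference, lo: float, hi: float):
    mask = (ref.axis >= lo) & (ref.axis <= hi)
    if not mask.any():
        raise ValueError("reference shares no points with the crop window")
    return ref.axis[mask], ref.mean_intensity[mask]


def cv_statistics(replicate_groups: list[list[RamanSpectrum]]) -> tuple[float, float]:
    """Repeatability and reproducibility CVs, in percent.

    Each spectrum is summarised by its total (summed) intensity. The
    repeatability CV is the mean over groups of the within-group sample
    CV (sd/mean); the reproducibility CV is the sample CV of the group
    means across groups. Groups with zero mean are excluded with a warning.
    """
    if len(replicate_groups) < 2:
        raise ValueError("need at least 2 replicate groups")
    within_cvs = []
    group_means = []
    for gi, group in enumerate(replicate_groups):
        if len(group) < 2:
            raise ValueError(f"group {gi} has fewer than 2 replicates")
        totals = np.array([float(np.sum(s.intensities)) for s in group])
        mean = totals.mean()
        if mean == 0:
            warnings.warn(f"replicate group {gi} has zero mean intensity; excluded")
            continue
        within_cvs.append(totals.std(ddof=1) / mean)
        group_means.append(mean)
    if len(group_means) < 2:
        raise ValueError("fewer than 2 usable replicate groups")
    group_means = np.array(group_means)
    repeatability = 100.0 * float(np.mean(within_cvs))
    reproducibility = 100.0 * float(group_means.std(ddof=1) / group_means.mean())
    return repeatability, reproducibility


def signal_ratio(
    samples: np.ndarray | SpectralDataset, ref: SubstrateReference
) -> tuple[np.ndarray, float]:
    """Per-wavenumber mean-sample / mean-reference intensity ratio and its mean.

    Wavenumbers with zero reference intensity are excluded with a warning.
    """
    matrix = samples.matrix if isinstance(samples, SpectralDataset) else np.asarray(samples)
    if matrix.shape[1] != len(ref.axis):
        raise ValueError("samples and reference are on different axes")
    sample_mean = matrix.mean(axis=0)
    ok = ref.mean_intensity != 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} wavenumbers with zero reference intensity excluded")
    ratio = np.full(len(ref.axis), np.nan)
    ratio[ok] = sample_mean[ok] / ref.mean_intensity[ok]
    return ratio, float(np.nanmean(ratio))
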