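"""Synthetic SERS spectrum generator for two-class CSF classification studies.

Emulates cerebrospinal-fluid spectra acquired on silver-nanoparticle
cellulose strips: a weak substrate background (roughly 62-fold below the
sample signal), Gaussian analyte bands whose amplitudes differ between
control and hydrocephalus classes, a smooth polynomial baseline drift,
additive detector noise, and three nested sources of multiplicative
variation — patient-to-patient (lognormal, CV ~60%), strip-to-strip
(reproducibility, CV ~5.5%), and position-within-strip (repeatability,
CV ~1.2%).

Every generator is deterministic given a seed, all intensities are clamped
non-negative, and :func:`generate_dataset` returns the planted ground truth
so downstream recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import RamanSpectrum, SpectralDataset, write_manifest, write_spectrum

__all__ = [
    "PeakSpec",
    "SimConfig",
    "default_peak_table",
    "default_substrate_peak_table",
    "generate_substrate_spectrum",
    "generate_csf_spectrum",
    "generate_dataset",
    "generate_replicate_set",
    "write_dataset",
]


@dataclass(frozen=True)
class PeakSpec:
    """A Gaussian band: position, width (sigma), and per-class amplitudes."""

    center: float
    width: float
    amplitude_control: float
    amplitude_case: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.amplitude_control < 0 or self.amplitude_case < 0:
            raise ValueError("peak amplitudes must be non-negative")


def default_peak_table() -> list[PeakSpec]:
    """Class-differential CSF bands.

    Control-elevated bands sit at 600, 790, 900, 930 and 1350 cm^-1 (the
    900/930 C-H bending bands are absent in the case class); case-elevated
    bands at 710, 800, 1320, 1476, 1540 and 1690 cm^-1, with the 800 and
    1476 cm^-1 bands carrying the largest differential. Amplitudes are
    simulation parameters, not measured values.
    """
    return [
        PeakSpec(600.0, 8.0, 1.0, 0.55),
        PeakSpec(710.0, 8.0, 0.5, 1.0),
        PeakSpec(790.0, 8.0, 1.0, 0.55),
        PeakSpec(800.0, 8.0, 0.4, 1.2),
        PeakSpec(900.0, 8.0, 0.8, 0.0),
        PeakSpec(930.0, 8.0, 0.8, 0.0),
        PeakSpec(1320.0, 8.0, 0.5, 1.0),
        PeakSpec(1350.0, 8.0, 1.0, 0.55),
        PeakSpec(1476.0, 8.0, 0.4, 1.2),
        PeakSpec(1540.0, 10.0, 0.5, 1.0),
        PeakSpec(1690.0, 10.0, 0.5, 1.0),
    ]


def default_substrate_peak_table() -> list[PeakSpec]:
    """Broad cellulose/AgNP background bands (identical for both classes)."""
    return [
        PeakSpec(900.0, 60.0, 1.0, 1.0),
        PeakSpec(1120.0, 50.0, 1.4, 1.4),
        PeakSpec(1380.0, 70.0, 0.9, 0.9),
        PeakSpec(1600.0, 45.0, 0.6, 0.6),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic acquisition.

    CV defaults follow the strip characterisation (repeatability 1.2%,
    reproducibility 5.5%), the patient-level heterogeneity (~60%), and the
    ~62-fold sample-to-substrate intensity ratio.
    """

    axis_lo: float = 550.0
    axis_hi: float = 1800.0
    n_points: int = 313
    peak_table: list[PeakSpec] = field(default_factory=default_peak_table)
    substrate_peak_table: list[PeakSpec] = field(default_factory=default_substrate_peak_table)
    target_signal_ratio: float = 61.89
    patient_cv: float = 0.60
    within_strip_cv: float = 0.012
    across_strip_cv: float = 0.055
    baseline_amplitude: float = 5.0
    noise_sd: float = 0.2
    substrate_offset: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.axis_lo >= self.axis_hi:
            raise ValueError("axis_lo must be < axis_hi")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        for cv in (self.patient_cv, self.within_strip_cv, self.across_strip_cv):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if self.target_signal_ratio <= 0:
            raise ValueError("target_signal_ratio must be positive")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ValueError("noise_sd and baseline_amplitude must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_lo, self.axis_hi, self.n_points)


def _gaussian_profile(axis: np.ndarray, peaks: list[PeakSpec], which: str) -> np.ndarray:
    out = np.zeros_like(axis)
    for p in peaks:
        amp = p.amplitude_control if which == "control" else p.amplitude_case
        if amp > 0:
            out += amp * np.exp(-0.5 * ((axis - p.center) / p.width) ** 2)
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with the given coefficient of variation.

    Still consumes one draw at cv=0 so that rng streams stay aligned across
    configurations (determinism contract).
    """
    sigma2 = np.log1p(cv**2)
    draw = rng.standard_normal(size)
    return np.exp(np.sqrt(sigma2) * draw - sigma2 / 2.0)


def _substrate_profile(config: SimConfig) -> np.ndarray:
    return config.substrate_offset + _gaussian_profile(
        config.axis, config.substrate_peak_table, "control"
    )


def _signal_scale(config: SimConfig) -> float:
    """Scale applied to analyte peaks + drift so that the expected sample mean
    intensity is target_signal_ratio times the substrate mean intensity."""
    sub_mean = float(np.mean(_substrate_profile(config)))
    axis = config.axis
    class_mean = 0.5 * (
        _gaussian_profile(axis, config.peak_table, "control")
        + _gaussian_profile(axis, config.peak_table, "case")
    )
    # expected drift mean: baseline_amplitude * E[u] with u~U(0.3, 1) (see _baseline_drift)
    drift_mean = config.baseline_amplitude * 0.65
    raw_mean = float(np.mean(class_mean)) + drift_mean
    if raw_mean <= 0:
        return 1.0
    return (config.target_signal_ratio - 1.0) * sub_mean / raw_mean


def _baseline_drift(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial background with random coefficients.

    Shaped to stay positive over the axis: amplitude * (u0 + sum of Chebyshev
    terms damped to keep the curve slowly varying), clamped at zero.
    """
    x = np.linspace(-1.0, 1.0, config.n_points)
    u0 = rng.uniform(0.3, 1.0)
    coefs = rng.uniform(-0.25, 0.25, size=3)
    drift = u0 + coefs[0] * x + coefs[1] * (2 * x**2 - 1) + coefs[2] * (4 * x**3 - 3 * x)
    return config.baseline_amplitude * np.clip(drift, 0.0, None)


def generate_substrate_spectrum(
    config: SimConfig,
    rng: np.random.Generator,
    strip_factor: float | None = None,
) -> RamanSpectrum:
    """Draw one blank-strip (substrate only) spectrum.

    Each call draws a fresh strip-level multiplier (reproducibility) unless
    ``strip_factor`` pins it, plus a position-level multiplier
    (repeatability) and additive noise.
    """
    config.validate()
    if strip_factor is None:
        strip_factor = float(_lognormal_factor(rng, config.across_strip_cv))
    position_factor = float(_lognormal_factor(rng, config.within_strip_cv))
    profile = _substrate_profile(config) * strip_factor * position_factor
    noise = config.noise_sd * rng.standard_normal(config.n_points)
    return RamanSpectrum(config.axis, np.clip(profile + noise, 0.0, None))


def generate_csf_spectrum(
    label: int,
    patient_effect: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> RamanSpectrum:
    """Draw one CSF-on-strip spectrum for a given class label.

    spectrum = substrate draw + patient_effect * class peaks + drift + noise,
    clamped non-negative. The rng consumption is identical for both labels,
    so with equal draws the two classes differ only at differential bands.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 (control) or 1 (case), got {label!r}")
    if patient_effect <= 0:
        raise ValueError("patient_effect must be positive")
    config.validate()
    substrate = generate_substrate_spectrum(config, rng)
    scale = _signal_scale(config)
    which = "control" if label == 0 else "case"
    peaks = scale * _gaussian_profile(config.axis, config.peak_table, which)
    drift = scale * _baseline_drift(config, rng)
    noise = config.noise_sd * rng.standard_normal(config.n_points)
    total = substrate.intensities + patient_effect * peaks + drift + noise
    return RamanSpectrum(config.axis, np.clip(total, 0.0, None), {"label": label})


def generate_dataset(
    n_control: int,
    n_case: int,
    config: SimConfig | None = None,
) -> tuple[SpectralDataset, dict]:
    """Simulate one spectrum per synthetic patient plus the ground truth.

    Patient effects are unit-mean lognormal with CV = ``config.patient_cv``.
    Returns the dataset and a record holding planted peaks, labels, patient
    effects and the seed, for recovery tests.
    """
    if n_control < 1 or n_case < 1:
        raise ValueError("need at least one patient per class")
    config = config if config is not None else SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = np.concatenate([np.zeros(n_control, dtype=int), np.ones(n_case, dtype=int)])
    effects = _lognormal_factor(rng, config.patient_cv, size=len(labels))
    rows = []
    for lab, eff in zip(labels, effects):
        rows.append(generate_csf_spectrum(int(lab), float(eff), config, rng).intensities)
    patient_ids = np.array([f"P{i:04d}" for i in range(len(labels))])
    dataset = SpectralDataset(
        axis=config.axis, matrix=np.vstack(rows), labels=labels, patient_ids=patient_ids
    )
    truth = {
        "peak_table": list(config.peak_table),
        "labels": labels.copy(),
        "patient_effects": effects.copy(),
        "signal_scale": _signal_scale(config),
        "seed": config.seed,
    }
    return dataset, truth


def generate_replicate_set(
    n_strips: int,
    n_positions: int,
    config: SimConfig | None = None,
) -> list[list[RamanSpectrum]]:
    """Blank-strip replicate structure: n_strips groups of n_positions spectra.

    One strip-level multiplier is drawn per strip and shared by its
    positions, mirroring the repeatability/reproducibility protocol of
    measuring several locations on each of several strips.
    """
    if n_strips < 2 or n_positions < 2:
        raise ValueError("need at least 2 strips and 2 positions")
    config = config if config is not None else SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups: list[list[RamanSpectrum]] = []
    for s in range(n_strips):
        strip_factor = float(_lognormal_factor(rng, config.across_strip_cv))
        group = []
        for p in range(n_positions):
            spec = generate_substrate_spectrum(config, rng, strip_factor=strip_factor)
            spec.meta.update({"strip_id": s, "position": p})
            group.append(spec)
        groups.append(group)
    return groups


def write_dataset(dataset: SpectralDataset, truth: dict, out_dir) -> "pd.DataFrame":
    """Persist a synthetic dataset: TSV spectra, CSV manifest, ground-truth JSON."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(dataset.n_samples):
        pid = str(dataset.patient_ids[i])
        rel = f"spectra/{pid}.tsv"
        write_spectrum(
            RamanSpectrum(dataset.axis, dataset.matrix[i]), out_dir / rel
        )
        records.append(
            {
                "sample_id": pid,
                "label": int(dataset.labels[i]),
                "patient_id": pid,
                "strip_id": i,
                "position": 0,
                "path": rel,
            }
        )
    manifest = pd.DataFrame.from_records(records)
    write_manifest(manifest, out_dir / "manifest.csv")
    truth_json = {
        "seed": int(truth["seed"]),
        "signal_scale": float(truth["signal_scale"]),
        "labels": [int(x) for x in truth["labels"]],
        "patient_effects": [float(x) for x in truth["patient_effects"]],
        "peak_table": [
            {
                "center": p.center,
                "width": p.width,
                "amplitude_control": p.amplitude_control,
                "amplitude_case": p.amplitude_case,
            }
            for p in truth["peak_table"]
        ],
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return manifest
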