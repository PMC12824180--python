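"""Reading and writing Raman spectra, manifests, and aligned datasets.

Spectra are plain two-column TSV files (wavenumber in cm^-1, intensity in
counts); ``#`` lines are comments. A manifest is a CSV with header
``sample_id,label,patient_id,strip_id,position,path`` binding each spectrum
file to its class label and acquisition metadata. :func:`load_dataset`
assembles a manifest into a :class:`SpectralDataset` on a shared wavenumber
grid, interpolating linearly where native axes differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SpectralDataset",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "load_dataset",
    "write_manifest",
]

MANIFEST_COLUMNS = ["sample_id", "label", "patient_id", "strip_id", "position", "path"]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; carries the line number."""


@dataclass
class RamanSpectrum:
    """One measured or synthetic spectrum on a strictly increasing wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError("wavenumbers and intensities must have equal length")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain missing or non-finite values")

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass
class SpectralDataset:
    """Aligned spectrum matrix with class labels, one row per patient."""

    axis: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.patient_ids = np.asarray(self.patient_ids)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.axis):
            raise ValueError("matrix column count must equal axis length")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels length must equal number of rows")
        if len(self.patient_ids) != self.matrix.shape[0]:
            raise ValueError("patient_ids length must equal number of rows")
        if self.labels.size and not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be in {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices: np.ndarray) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            axis=self.axis.copy(),
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            patient_ids=self.patient_ids[idx],
        )


def read_spectrum(path: str | Path, meta: dict | None = None) -> RamanSpectrum:
    """Parse a two-column TSV spectrum file.

    Rows are sorted into ascending wavenumber order if needed. A malformed
    row raises :class:`SpectrumParseError` naming the offending line.
    """
    path = Path(path)
    wavenumbers: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected two columns, got {len(parts)}"
                )
            try:
                wavenumbers.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value in {stripped!r}"
                ) from exc
    if len(wavenumbers) < 2:
        raise ValueError(f"{path}: spectrum needs at least 2 points, got {len(wavenumbers)}")
    wn = np.asarray(wavenumbers)
    inten = np.asarray(intensities)
    order = np.argsort(wn, kind="stable")
    return RamanSpectrum(wn[order], inten[order], dict(meta or {}))


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as tab-separated wavenumber/intensity pairs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(w)!r}\t{float(i)!r}\n")


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    rows.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def common_axis(spectra: list[RamanSpectrum]) -> np.ndarray:
    """Shared uniform grid over the intersection range of all spectra.

    Grid spacing is the median native spacing across spectra so that
    interpolation neither invents nor discards much resolution.
    """
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if lo >= hi:
        raise ValueError("spectra share no overlapping wavenumber range")
    spacings = np.concatenate([np.diff(s.wavenumbers) for s in spectra])
    step = float(np.median(spacings))
    n = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def load_dataset(manifest_path: str | Path, spectra_dir: str | Path | None = None) -> SpectralDataset:
    """Load every spectrum listed in a manifest onto a common axis.

    Paths in the manifest are resolved relative to ``spectra_dir`` (defaults
    to the manifest's directory). Duplicate patient ids violate the
    one-spectrum-per-patient contract and raise.
    """
    manifest_path = Path(manifest_path)
    base = Path(spectra_dir) if spectra_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path, dtype={"patient_id": str, "sample_id": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    dup = manifest["patient_id"][manifest["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id(s) in manifest: {sorted(set(dup))}")

    spectra = []
    for _, row in manifest.iterrows():
        fp = base / str(row["path"])
        if not fp.exists():
            raise FileNotFoundError(f"spectrum file for sample_id={row['sample_id']!r} not found: {fp}")
        spectra.append(read_spectrum(fp, meta=row.to_dict()))

    axis = common_axis(spectra)
    identical = all(
        len(s) == len(axis) and np.allclose(s.wavenumbers, axis) for s in spectra
    )
    if identical:
        matrix = np.vstack([s.intensities for s in spectra])
    else:
        matrix = np.vstack(
            [np.interp(axis, s.wavenumbers, s.intensities) for s in spectra]
        )
    return SpectralDataset(
        axis=axis,
        matrix=matrix,
        labels=manifest["label"].to_numpy(dtype=int),
        patient_ids=manifest["patient_id"].to_numpy(),
    )
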