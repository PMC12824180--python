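"""Run configuration: one YAML-loadable object covering simulation,
preprocessing, scoring and grid toggles, plus a master seed.

The master seed deterministically spawns sub-seeds for simulation,
splitting, fold assignment and tree randomness, so each stage is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .preprocess import PreprocessParams
from .selection import ScoringParams
from .synthetic import SimConfig

__all__ = ["RunConfig", "derive_seeds"]

_SIM_KEYS = {
    "axis_lo", "axis_hi", "n_points", "target_signal_ratio", "patient_cv",
    "within_strip_cv", "across_strip_cv", "baseline_amplitude", "noise_sd",
    "substrate_offset",
}


@dataclass
class RunConfig:
    seed: int = 0
    n_control: int = 70
    n_case: int = 47
    n_reference_strips: int = 10
    test_fraction: float = 0.3
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    reductions: tuple = ("pca", "pls")
    dims: tuple = tuple(range(1, 11))
    families: tuple = ("LDA", "QDA", "SVM", "RF")
    rf_n_trees: tuple = tuple(range(100, 1001, 100))

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if not self.families:
            raise ValueError("at least one classifier family must be enabled")
        non_rf = [f for f in self.families if f != "RF"]
        if non_rf and (not self.reductions or not self.dims):
            raise ValueError("reduction families enabled but no reductions/dims configured")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one patient per class")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {
            "seed", "n_control", "n_case", "n_reference_strips", "test_fraction",
            "sim", "preprocess", "scoring", "reductions", "dims", "families",
            "rf_n_trees",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("seed", "n_control", "n_case", "n_reference_strips", "test_fraction"):
            if key in raw:
                kwargs[key] = raw[key]
        if "sim" in raw:
            sim_raw = dict(raw["sim"])
            bad = set(sim_raw) - _SIM_KEYS
            if bad:
                raise ValueError(f"unknown sim keys: {sorted(bad)}")
            kwargs["sim"] = SimConfig(**sim_raw)
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessParams(**raw["preprocess"])
        if "scoring" in raw:
            kwargs["scoring"] = ScoringParams(**raw["scoring"])
        for key in ("reductions", "dims", "families", "rf_n_trees"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "n_control": self.n_control,
            "n_case": self.n_case,
            "n_reference_strips": self.n_reference_strips,
            "test_fraction": self.test_fraction,
            "sim": {k: v for k, v in asdict(self.sim).items() if k in _SIM_KEYS},
            "preprocess": asdict(self.preprocess),
            "scoring": asdict(self.scoring),
            "reductions": list(self.reductions),
            "dims": list(self.dims),
            "families": list(self.families),
            "rf_n_trees": list(self.rf_n_trees),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def derive_seeds(master: int) -> dict:
    """Spawn named sub-seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master).generate_state(4, dtype=np.uint64)
    names = ("simulate", "split", "folds", "classifier")
    return {name: int(s % (2**31)) for name, s in zip(names, state)}
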