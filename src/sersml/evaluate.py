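"""Held-out evaluation: confusion matrix, metric panel, ROC, and the
feature-importance spectral report.

The positive class is hydrocephalus (label 1). Metrics are computed as
fractions; :func:`format_percent` renders them the conventional way
(x100, two decimals). Undefined metrics (zero denominators) are reported
as NaN with an explicit flag, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import wba as _wba

__all__ = [
    "Confusion",
    "EvaluationReport",
    "confusion_matrix",
    "metric_panel",
    "roc_curve",
    "importance_report",
    "format_percent",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class EvaluationReport:
    confusion: Confusion
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    wba: float
    undefined: list = field(default_factory=list)
    roc_points: list | None = None
    auc: float | None = None


def confusion_matrix(true_labels, predicted_labels) -> Confusion:
    """Binary confusion counts with class 1 (hydrocephalus) as positive."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if len(y) != len(p):
        raise ValueError("label vectors must have equal length")
    for arr, name in ((y, "true"), (p, "predicted")):
        if arr.size and not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} labels must be in {{0, 1}}")
    return Confusion(
        tp=int(np.sum((y == 1) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
    )


def metric_panel(confusion: Confusion) -> EvaluationReport:
    """Accuracy, sensitivity, specificity, precision and WBA from counts."""
    c = confusion
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    # WBA delegates to the selection module on a reconstructed label vector
    y = np.array([1] * (c.tp + c.fn) + [0] * (c.tn + c.fp))
    p = np.array([1] * c.tp + [0] * c.fn + [0] * c.tn + [1] * c.fp)
    wba_val = _wba(y, p) if (c.tp + c.fn) > 0 and (c.tn + c.fp) > 0 else float("nan")
    if np.isnan(wba_val):
        undefined.append("wba")
    return EvaluationReport(
        confusion=c,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        wba=wba_val,
        undefined=undefined,
    )


def roc_curve(scores, true_labels) -> tuple[list[tuple[float, float]], float, bool]:
    """ROC points (FPR, TPR) at midpoint thresholds, trapezoidal AUC.

    Returns (points, auc, degenerate). Constant scores give a single chance
    segment with AUC 0.5, flagged degenerate. The trapezoidal AUC equals
    the pairwise Mann-Whitney probability with ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    if len(distinct) == 1:
        return [(0.0, 0.0), (1.0, 1.0)], 0.5, True
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[-1] + 1.0], mids[::-1], [distinct[0] - 1.0]))
    points = []
    for t in thresholds:
        pred = s >= t
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        points.append((float(fpr), float(tpr)))
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc, False


def importance_report(
    importances: np.ndarray,
    axis: np.ndarray,
    control_mean: np.ndarray,
    case_mean: np.ndarray,
    top_m: int = 5,
    min_separation: float = 20.0,
) -> tuple[pd.DataFrame, list[float]]:
    """Tabulate per-wavenumber importance against the two group means.

    Returns the full table (one row per wavenumber) plus the top-``top_m``
    band positions, greedily selected in decreasing importance with bands
    closer than ``min_separation`` cm^-1 to an already chosen one merged
    into it. All-zero importances yield an empty band list.
    """
    importances = np.asarray(importances, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if not (len(importances) == len(axis) == len(control_mean) == len(case_mean)):
        raise ValueError("importances, axis and group means must share length")
    table = pd.DataFrame(
        {
            "wavenumber": axis,
            "control_mean": np.asarray(control_mean, dtype=float),
            "case_mean": np.asarray(case_mean, dtype=float),
            "importance": importances,
        }
    )
    bands: list[float] = []
    if importances.sum() > 0:
        for idx in np.argsort(-importances, kind="stable"):
            if importances[idx] == 0:
                break
            w = float(axis[idx])
            if all(abs(w - b) >= min_separation for b in bands):
                bands.append(w)
            if len(bands) >= top_m:
                break
    return table, bands


def format_percent(value: float) -> str:
    """Render a fraction as a percentage with two decimals, NaN-safe."""
    if np.isnan(value):
        return "undefined"
    return f"{100.0 * value:.2f}%"
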