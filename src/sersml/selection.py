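"""Model selection: stratified splitting, stratified k-fold CV, hyperparameter
grids, and the overfitting-penalized weighted-balanced-accuracy score.

The selection criterion for one hyperparameter combination is

    Score = MWBA - lambda * (TrainAcc - ValAcc)

where MWBA is the median over the k cross-validation folds of the weighted
balanced accuracy (WBA), TrainAcc/ValAcc are the mean training-subset and
validation-fold accuracies over the same folds, and lambda (default 2)
penalizes the train-validation gap that signals overfitting. WBA combines
one-vs-rest per-class balanced accuracies with inverse-class-size weights

    omega_i = (1/N_i) / sum_j (1/N_j),

so minority classes count as much as majority ones; for two classes WBA
reduces to the plain balanced accuracy (sensitivity + specificity) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import chemometrics, classifiers
from .classifiers import ClassifierSpec
from .io import SpectralDataset

__all__ = [
    "SplitPlan",
    "ScoringParams",
    "FoldScores",
    "ClassWeights",
    "GridPoint",
    "SelectionResult",
    "stratified_split",
    "stratified_kfold",
    "class_weights",
    "wba",
    "mwba",
    "score",
    "build_grids",
    "grid_search",
]


@dataclass
class SplitPlan:
    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    train_counts: dict
    test_counts: dict


@dataclass
class ScoringParams:
    penalty_lambda: float = 2.0
    k_folds: int = 10

    def __post_init__(self) -> None:
        if self.penalty_lambda < 0:
            raise ValueError("penalty_lambda must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class FoldScores:
    wba_per_fold: np.ndarray
    train_acc_per_fold: np.ndarray
    val_acc_per_fold: np.ndarray


@dataclass
class ClassWeights:
    omega: np.ndarray
    class_counts: np.ndarray


@dataclass(frozen=True)
class GridPoint:
    """One candidate: a reduction configuration plus a classifier spec.

    ``reduction`` is "pca", "pls" or None (RF runs on the full spectrum).
    """

    reduction: str | None
    n_components: int | None
    spec: ClassifierSpec


@dataclass
class SelectionResult:
    table: "object"  # pandas.DataFrame: one row per grid point
    winner: GridPoint
    winner_scores: FoldScores


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` across classes proportionally to ``counts``."""
    quotas = counts / counts.sum() * total
    alloc = np.floor(quotas).astype(int)
    rem = total - alloc.sum()
    if rem > 0:
        order = np.argsort(-(quotas - alloc), kind="stable")
        alloc[order[:rem]] += 1
    return alloc


def stratified_split(
    labels: np.ndarray,
    patient_ids: np.ndarray | None = None,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> SplitPlan:
    """Patient-level stratified train/test split.

    The total test size is ceil(test_fraction * N); per-class test counts
    follow largest-remainder apportionment of the class proportions, and
    membership within each class is randomized by ``seed``. For 70 controls
    and 47 cases at fraction 0.3 this yields test counts (22, 14) and
    training counts (48, 33).
    """
    labels = np.asarray(labels, dtype=int)
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    if patient_ids is not None:
        patient_ids = np.asarray(patient_ids)
        if len(np.unique(patient_ids)) != len(patient_ids):
            raise ValueError("one observation per patient required")
    total_test = math.ceil(test_fraction * len(labels))
    if total_test == 0 or total_test >= len(labels):
        raise ValueError("test_fraction leaves an empty partition")
    test_counts = _largest_remainder(counts, total_test)
    rng = np.random.default_rng(seed)
    test_idx = []
    for c, n_test in zip(classes, test_counts):
        members = np.flatnonzero(labels == c)
        test_idx.append(rng.permutation(members)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
    return SplitPlan(
        train_indices=train_idx,
        test_indices=test_idx,
        test_fraction=test_fraction,
        train_counts={int(c): int(np.sum(labels[train_idx] == c)) for c in classes},
        test_counts={int(c): int(np.sum(labels[test_idx] == c)) for c in classes},
    )


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint stratified validation folds over indices 0..n-1."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot build {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros(len(labels)), labels)]


def class_weights(class_counts) -> ClassWeights:
    """Inverse-count class weights, normalized to sum to one."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("all class counts must be >= 1")
    inv = 1.0 / counts
    return ClassWeights(omega=inv / inv.sum(), class_counts=counts.astype(int))


def wba(true_labels, predicted_labels, class_counts=None) -> float:
    """Weighted balanced accuracy over one-vs-rest class confusion matrices.

    Each class's balanced accuracy (mean of its one-vs-rest sensitivity and
    specificity) is weighted by omega_i proportional to 1/N_i. For two
    classes this equals (sensitivity + specificity) / 2 regardless of the
    weights. ``class_counts`` may override the observed counts (documented
    switch for alternative weighting conventions).
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if len(y) != len(p):
        raise ValueError("label vectors must have equal length")
    classes = np.unique(y)
    if not np.all(np.isin(p, classes)):
        raise ValueError("predictions contain labels absent from true_labels")
    counts = (
        np.array([np.sum(y == c) for c in classes])
        if class_counts is None
        else np.asarray(class_counts, dtype=float)
    )
    omega = class_weights(counts).omega
    total = 0.0
    for w, c in zip(omega, classes):
        pos = y == c
        neg = ~pos
        tp = np.sum(pos & (p == c))
        fn = np.sum(pos & (p != c))
        tn = np.sum(neg & (p != c))
        fp = np.sum(neg & (p == c))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) > 0 else 1.0
        total += w * 0.5 * (sens + spec)
    return float(total)


def mwba(wba_per_fold) -> float:
    """Median of the fold-wise WBA values (mean of central pair for even k)."""
    vals = np.asarray(wba_per_fold, dtype=float)
    if vals.size == 0:
        raise ValueError("mwba needs at least one fold value")
    return float(np.median(vals))


def score(
    mwba_value: float,
    mean_train_acc: float,
    mean_val_acc: float,
    penalty_lambda: float = 2.0,
) -> float:
    """Selection score: MWBA minus lambda times the train-validation gap."""
    for v in (mean_train_acc, mean_val_acc):
        if not (0.0 <= v <= 1.0):
            raise ValueError("accuracies must lie in [0, 1]")
    return float(mwba_value - penalty_lambda * (mean_train_acc - mean_val_acc))


def _log_grid(lo_exp: int, hi_exp: int) -> list[float]:
    return [10.0**e for e in range(lo_exp, hi_exp + 1)]


def build_grids(
    reductions: tuple[str, ...] = ("pca", "pls"),
    dims: tuple[int, ...] = tuple(range(1, 11)),
    families: tuple[str, ...] = ("LDA", "QDA", "SVM", "RF"),
    rf_n_trees: tuple[int, ...] = tuple(range(100, 1001, 100)),
) -> list[GridPoint]:
    """Enumerate the full hyperparameter search space in deterministic order.

    Per reduction (PCA/PLS) and dimensionality 1-10: LDA shrinkage
    {0, 0.25, ..., 1 -> capped below 1}, QDA shrinkage {0, 0.1, ..., 0.9},
    linear SVM C {0, 0.25, ..., 1}, polynomial (degree 3) and RBF SVM with
    C on 10^-3..10^3 and gamma on 10^-6..10^1 integer-exponent log grids.
    RF runs on the full feature set over n_trees x min_samples_split
    {20,30,40,50} x min_samples_leaf {5,10,15,20} x max_features
    {log2, sqrt, all}.
    """
    points: list[GridPoint] = []
    lda_c = [0.0, 0.25, 0.5, 0.75, 1.0]
    qda_r = [round(0.1 * i, 1) for i in range(10)]
    svm_c_log = _log_grid(-3, 3)
    svm_gamma_log = _log_grid(-6, 1)
    for red in reductions:
        for m in dims:
            for fam in families:
                if fam == "LDA":
                    # shrinkage of exactly 1 collapses the covariance; cap just below
                    for c in lda_c:
                        reg = min(c, 1.0 - 1e-9)
                        points.append(GridPoint(red, m, ClassifierSpec("LDA", reg=reg)))
                elif fam == "QDA":
                    for r in qda_r:
                        points.append(GridPoint(red, m, ClassifierSpec("QDA", reg=r)))
                elif fam == "SVM":
                    for c in lda_c:
                        points.append(
                            GridPoint(red, m, ClassifierSpec("SVM", kernel="linear", C=c))
                        )
                    for kernel in ("poly3", "rbf"):
                        for c in svm_c_log:
                            for g in svm_gamma_log:
                                points.append(
                                    GridPoint(
                                        red, m,
                                        ClassifierSpec("SVM", kernel=kernel, C=c, gamma=g),
                                    )
                                )
    if "RF" in families:
        for n in rf_n_trees:
            for mss in (20, 30, 40, 50):
                for msl in (5, 10, 15, 20):
                    for mf in ("log2", "sqrt", "all"):
                        points.append(
                            GridPoint(
                                None, None,
                                ClassifierSpec(
                                    "RF", n_trees=n, min_samples_split=mss,
                                    min_samples_leaf=msl, max_features=mf,
                                ),
                            )
                        )
    return points


def _fit_reduction(point: GridPoint, x: np.ndarray, y: np.ndarray):
    if point.reduction is None:
        return None
    if point.reduction == "pca":
        return chemometrics.pca_fit(x, point.n_components)
    if point.reduction == "pls":
        return chemometrics.pls_fit(x, y, point.n_components)
    raise ValueError(f"unknown reduction {point.reduction!r}")


def grid_search(
    train_dataset: SpectralDataset,
    grids: list[GridPoint],
    scoring_params: ScoringParams | None = None,
    seed: int = 0,
    leakage_hook=None,
) -> SelectionResult:
    """Score every grid point by stratified k-fold CV and pick the argmax.

    For each fold the reduction is fitted on the fold-training subset only
    and the validation fold is merely transformed — validation indices
    never enter any fit. A grid point whose fit fails on any fold is scored
    -inf and flagged. Ties go to the first point in enumeration order.

    ``leakage_hook(fold_train_idx, fold_val_idx)`` is called before every
    fold fit, for instrumentation and leakage assertions in tests.
    """
    import pandas as pd

    params = scoring_params if scoring_params is not None else ScoringParams()
    if not grids:
        raise ValueError("empty grid")
    x_full = train_dataset.matrix
    y_full = train_dataset.labels
    folds = stratified_kfold(y_full, params.k_folds, seed=seed)
    all_idx = np.arange(len(y_full))
    fold_splits = [(np.setdiff1d(all_idx, val), val) for val in folds]

    # group grid points by reduction config so each fold's reduction is
    # fitted once and shared by all classifiers using it
    groups: dict[tuple, list[int]] = {}
    for gi, point in enumerate(grids):
        groups.setdefault((point.reduction, point.n_components), []).append(gi)

    n_points = len(grids)
    wba_mat = np.full((n_points, params.k_folds), np.nan)
    train_mat = np.full((n_points, params.k_folds), np.nan)
    val_mat = np.full((n_points, params.k_folds), np.nan)
    failed = np.zeros(n_points, dtype=bool)

    for key, members in groups.items():
        for fi, (tr, va) in enumerate(fold_splits):
            if leakage_hook is not None:
                leakage_hook(tr, va)
            x_tr_raw, y_tr = x_full[tr], y_full[tr]
            x_va_raw, y_va = x_full[va], y_full[va]
            sample_point = grids[members[0]]
            try:
                red = _fit_reduction(sample_point, x_tr_raw, y_tr)
            except Exception:
                failed[members] = True
                continue
            if red is None:
                x_tr, x_va = x_tr_raw, x_va_raw
            else:
                x_tr, x_va = red.transform(x_tr_raw), red.transform(x_va_raw)

            rf_members = [gi for gi in members if grids[gi].spec.family == "RF"]
            other_members = [gi for gi in members if grids[gi].spec.family != "RF"]

            for gi in other_members:
                if failed[gi]:
                    continue
                point = grids[gi]
                try:
                    model = classifiers.fit(point.spec, x_tr, y_tr, seed=seed)
                    pred_tr = classifiers.predict(model, x_tr)
                    pred_va = classifiers.predict(model, x_va)
                except Exception:
                    failed[gi] = True
                    continue
                wba_mat[gi, fi] = wba(y_va, pred_va)
                train_mat[gi, fi] = float(np.mean(pred_tr == y_tr))
                val_mat[gi, fi] = float(np.mean(pred_va == y_va))

            # RF points sharing everything but n_trees reuse one forest: the
            # first n trees of a seeded forest ARE the n-tree forest, so each
            # smaller ensemble is scored from cumulative per-tree votes
            by_base: dict[tuple, list[int]] = {}
            for gi in rf_members:
                if failed[gi]:
                    continue
                s = grids[gi].spec
                by_base.setdefault(
                    (s.min_samples_split, s.min_samples_leaf, s.max_features, s.max_depth),
                    [],
                ).append(gi)
            for base_key, gis in by_base.items():
                gis_sorted = sorted(gis, key=lambda g: grids[g].spec.n_trees)
                spec_max = grids[gis_sorted[-1]].spec
                try:
                    model = classifiers.fit(spec_max, x_tr, y_tr, seed=seed)
                    votes_tr = np.cumsum(
                        classifiers.rf_tree_predictions(model, x_tr), axis=0
                    )
                    votes_va = np.cumsum(
                        classifiers.rf_tree_predictions(model, x_va), axis=0
                    )
                except Exception:
                    for gi in gis_sorted:
                        failed[gi] = True
                    continue
                for gi in gis_sorted:
                    n = grids[gi].spec.n_trees
                    pred_tr = (2 * votes_tr[n - 1] > n).astype(int)
                    pred_va = (2 * votes_va[n - 1] > n).astype(int)
                    wba_mat[gi, fi] = wba(y_va, pred_va)
                    train_mat[gi, fi] = float(np.mean(pred_tr == y_tr))
                    val_mat[gi, fi] = float(np.mean(pred_va == y_va))

    rows = []
    best_gi, best_score = None, -np.inf
    for gi, point in enumerate(grids):
        if failed[gi] or np.isnan(wba_mat[gi]).any():
            failed[gi] = True
            mwba_v = gap = sc = -np.inf
        else:
            mwba_v = mwba(wba_mat[gi])
            gap = float(np.mean(train_mat[gi]) - np.mean(val_mat[gi]))
            sc = score(mwba_v, float(np.mean(train_mat[gi])), float(np.mean(val_mat[gi])),
                       params.penalty_lambda)
            if sc > best_score:
                best_gi, best_score = gi, sc
        rows.append(
            {
                "index": gi,
                "reduction": point.reduction or "",
                "n_components": point.n_components or 0,
                "family": point.spec.family,
                "spec": _spec_str(point.spec),
                "mwba": mwba_v,
                "gap": gap,
                "score": sc,
                "failed": bool(failed[gi]),
            }
        )
    if best_gi is None:
        raise RuntimeError("every grid point failed to fit")
    table = pd.DataFrame(rows)
    winner_scores = FoldScores(
        wba_per_fold=wba_mat[best_gi].copy(),
        train_acc_per_fold=train_mat[best_gi].copy(),
        val_acc_per_fold=val_mat[best_gi].copy(),
    )
    return SelectionResult(table=table, winner=grids[best_gi], winner_scores=winner_scores)


def _spec_str(spec: ClassifierSpec) -> str:
    parts = [spec.family]
    for name in ("kernel", "C", "gamma", "reg", "n_trees", "min_samples_split",
                 "min_samples_leaf", "max_features", "max_depth"):
        v = getattr(spec, name)
        if v is not None:
            parts.append(f"{name}={v}")
    return " ".join(parts)
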