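import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sersml.classifiers import ClassifierSpec
from sersml.io import SpectralDataset
from sersml.selection import (
    GridPoint,
    ScoringParams,
    build_grids,
    class_weights,
    grid_search,
    mwba,
    score,
    stratified_kfold,
    stratified_split,
    wba,
)


class TestStratifiedSplit:
    def test_study_counts_reproduced(self):
        labels = np.array([0] * 70 + [1] * 47)
        plan = stratified_split(labels, test_fraction=0.3, seed=0)
        assert plan.test_counts == {0: 22, 1: 14}
        assert plan.train_counts == {0: 48, 1: 33}

    def test_balanced_symmetric_case(self):
        labels = np.array([0] * 10 + [1] * 10)
        plan = stratified_split(labels, test_fraction=0.5, seed=1)
        assert plan.test_counts == {0: 5, 1: 5}

    def test_zero_fraction_rejected(self):
        labels = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError):
            stratified_split(labels, test_fraction=0.0)

    def test_partitions_disjoint_and_exhaustive(self):
        labels = np.array([0] * 31 + [1] * 17)
        plan = stratified_split(labels, test_fraction=0.3, seed=3)
        combined = np.sort(np.concatenate([plan.train_indices, plan.test_indices]))
        np.testing.assert_array_equal(combined, np.arange(48))

    def test_counts_deterministic_membership_seeded(self):
        labels = np.array([0] * 70 + [1] * 47)
        a = stratified_split(labels, test_fraction=0.3, seed=0)
        b = stratified_split(labels, test_fraction=0.3, seed=1)
        assert a.test_counts == b.test_counts
        assert not np.array_equal(a.test_indices, b.test_indices)

    def test_duplicate_patients_rejected(self):
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="per patient"):
            stratified_split(labels, patient_ids=np.array(["a", "a", "b", "c"]))


class TestStratifiedKfold:
    def test_training_fold_class_balance(self):
        labels = np.array([0] * 48 + [1] * 33)
        folds = stratified_kfold(labels, 10, seed=0)
        for fold in folds:
            n0 = int((labels[fold] == 0).sum())
            n1 = int((labels[fold] == 1).sum())
            assert n0 in (4, 5)
            assert n1 in (3, 4)

    def test_one_of_each_class_per_fold_when_exact(self):
        labels = np.array([0, 1] * 5)
        folds = stratified_kfold(labels, 5, seed=0)
        for fold in folds:
            assert len(fold) == 2
            assert sorted(labels[fold]) == [0, 1]

    def test_partition_contract(self):
        labels = np.array([0] * 25 + [1] * 20)
        folds = stratified_kfold(labels, 5, seed=2)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(45))

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([0] * 20 + [1] * 4)
        with pytest.raises(ValueError):
            stratified_kfold(labels, 5)


class TestClassWeights:
    def test_study_test_composition(self):
        cw = class_weights([22, 14])
        np.testing.assert_allclose(cw.omega, [14 / 36, 22 / 36])

    def test_equal_counts(self):
        np.testing.assert_allclose(class_weights([7, 7]).omega, [0.5, 0.5])

    def test_single_class(self):
        np.testing.assert_allclose(class_weights([9]).omega, [1.0])

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights([5, 0])

    def test_sums_to_one(self):
        assert class_weights([3, 11, 29]).omega.sum() == pytest.approx(1.0)


def oracle_wba(y, p):
    """Independent oracle: explicit per-class one-vs-rest confusion arithmetic."""
    classes = sorted(set(y))
    inv = [1.0 / y.count(c) for c in classes]
    omegas = [v / sum(inv) for v in inv]
    total = 0.0
    for w, c in zip(omegas, classes):
        tp = sum(1 for yi, pi in zip(y, p) if yi == c and pi == c)
        fn = sum(1 for yi, pi in zip(y, p) if yi == c and pi != c)
        tn = sum(1 for yi, pi in zip(y, p) if yi != c and pi != c)
        fp = sum(1 for yi, pi in zip(y, p) if yi != c and pi == c)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        total += w * 0.5 * (sens + spec)
    return total


class TestWba:
    def test_exhaustive_oracle_all_prediction_vectors_n8(self):
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        for bits in itertools.product((0, 1), repeat=8):
            p = list(bits)
            assert wba(y, p) == pytest.approx(oracle_wba(y, p), abs=1e-12)

    def test_exhaustive_oracle_imbalanced_n8(self):
        y = [0, 0, 0, 0, 0, 1, 1, 1]
        for bits in itertools.product((0, 1), repeat=8):
            p = list(bits)
            assert wba(y, p) == pytest.approx(oracle_wba(y, p), abs=1e-12)

    def test_study_fixture_one_false_positive(self):
        y = np.array([0] * 22 + [1] * 14)
        p = y.copy()
        p[0] = 1
        assert 100 * wba(y, p) == pytest.approx(97.73, abs=0.005)

    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        assert wba(y, y) == 1.0

    def test_constant_prediction_is_chance(self):
        y = np.array([0] * 6 + [1] * 2)
        assert wba(y, np.ones(8, dtype=int)) == pytest.approx(0.5)

    def test_two_class_equals_balanced_accuracy_any_weights(self):
        y = np.array([0] * 10 + [1] * 4)
        p = np.array([0] * 8 + [1] * 2 + [1] * 3 + [0])
        sens = 3 / 4
        spec = 8 / 10
        assert wba(y, p) == pytest.approx(0.5 * (sens + spec))
        # overriding the class counts (alternative weighting) cannot change
        # the two-class value
        assert wba(y, p, class_counts=[7, 7]) == pytest.approx(0.5 * (sens + spec))

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            wba([0, 0, 1], [0, 2, 1])


class TestMwba:
    @pytest.mark.parametrize(
        "folds,expected",
        [((0.9, 0.7, 0.8), 0.8), ((0.6, 1.0, 0.8, 0.9), 0.85), ((0.4, 0.4, 0.4), 0.4)],
    )
    def test_examples(self, folds, expected):
        assert mwba(folds) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mwba([])

    def test_equals_sorting_based_median_randomized(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 15))
            vals = rng.random(k)
            srt = np.sort(vals)
            if k % 2:
                expected = srt[k // 2]
            else:
                expected = 0.5 * (srt[k // 2 - 1] + srt[k // 2])
            assert mwba(vals) == pytest.approx(expected, abs=1e-15)


class TestScore:
    def test_formula(self):
        assert score(0.95, 0.99, 0.93, 2.0) == pytest.approx(0.83)

    def test_zero_gap(self):
        assert score(0.88, 0.9, 0.9, 2.0) == pytest.approx(0.88)

    def test_zero_lambda(self):
        assert score(0.7, 1.0, 0.5, 0.0) == pytest.approx(0.7)

    @settings(derandomize=True, max_examples=50)
    @given(
        m=st.floats(0, 1), tr=st.floats(0, 1), va=st.floats(0, 1),
        lam=st.floats(0, 5), eps=st.floats(0.001, 0.2),
    )
    def test_monotone_in_gap_and_mwba(self, m, tr, va, lam, eps):
        base = score(m, tr, va, lam)
        if tr + eps <= 1:
            assert score(m, tr + eps, va, lam) <= base
        if m + eps <= 1:
            assert score(m + eps, tr, va, lam) >= base


class TestBuildGrids:
    def test_subgrid_sizes(self):
        grid = build_grids(reductions=("pca",), dims=(1,), families=("LDA", "QDA", "SVM"))
        fams = [g.spec.family for g in grid]
        assert fams.count("LDA") == 5
        assert fams.count("QDA") == 10
        linear = [g for g in grid if g.spec.family == "SVM" and g.spec.kernel == "linear"]
        poly = [g for g in grid if g.spec.kernel == "poly3"]
        rbf = [g for g in grid if g.spec.kernel == "rbf"]
        assert len(linear) == 5
        assert len(poly) == 7 * 8
        assert len(rbf) == 7 * 8

    def test_rf_grid_size(self):
        grid = build_grids(families=("RF",), rf_n_trees=tuple(range(100, 1001, 100)))
        assert len(grid) == 10 * 4 * 4 * 3
        assert all(g.reduction is None for g in grid)

    def test_enumeration_deterministic(self):
        a = build_grids()
        b = build_grids()
        assert a == b


def _toy_dataset(rng, n0=30, n1=30, n_points=24, rf_friendly=False):
    axis = np.linspace(550, 1800, n_points)
    X = rng.standard_normal((n0 + n1, n_points)) * 0.3
    y = np.array([0] * n0 + [1] * n1)
    if rf_friendly:
        # class 0 splits into two flanks around class 1 on one coordinate:
        # no linear boundary separates them, but two axis-aligned splits do
        signs = rng.choice([-1.0, 1.0], size=n0)
        X[:n0, 5] += signs * 4.0
    else:
        X[y == 1, 5] += 3.0
    return SpectralDataset(axis=axis, matrix=X, labels=y,
                           patient_ids=np.array([f"p{i}" for i in range(n0 + n1)]))


class TestGridSearch:
    def test_single_point_wins(self, rng):
        ds = _toy_dataset(rng)
        grid = [GridPoint("pca", 2, ClassifierSpec("LDA", reg=0.0))]
        res = grid_search(ds, grid, ScoringParams(k_folds=5), seed=0)
        assert res.winner == grid[0]
        assert len(res.table) == 1

    def test_tie_break_first_in_order(self, rng):
        ds = _toy_dataset(rng)
        pt = GridPoint("pca", 2, ClassifierSpec("LDA", reg=0.0))
        res = grid_search(ds, [pt, pt], ScoringParams(k_folds=5), seed=0)
        assert res.table.iloc[0]["score"] == res.table.iloc[1]["score"]
        assert int(res.table[res.table.score == res.table.score.max()].index[0]) == 0
        assert res.winner == pt

    def test_rf_favourable_signal_scores_rf_at_least_lda(self, rng):
        ds = _toy_dataset(rng, n0=40, n1=40, rf_friendly=True)
        grid = [
            GridPoint(None, None, ClassifierSpec("RF", n_trees=100, min_samples_split=2,
                                                 min_samples_leaf=1, max_features="sqrt")),
            GridPoint("pca", 3, ClassifierSpec("LDA", reg=0.0)),
        ]
        res = grid_search(ds, grid, ScoringParams(k_folds=5), seed=0)
        t = res.table
        assert t[t.family == "RF"].score.max() >= t[t.family == "LDA"].score.max()

    def test_failed_grid_point_flagged_not_fatal(self, rng):
        ds = _toy_dataset(rng)
        grid = [
            GridPoint("pca", 2, ClassifierSpec("SVM", kernel="linear", C=0.0)),
            GridPoint("pca", 2, ClassifierSpec("LDA", reg=0.0)),
        ]
        res = grid_search(ds, grid, ScoringParams(k_folds=5), seed=0)
        assert bool(res.table.iloc[0]["failed"])
        assert res.table.iloc[0]["score"] == -np.inf
        assert res.winner == grid[1]

    def test_determinism(self, rng):
        ds = _toy_dataset(rng)
        grid = build_grids(reductions=("pca",), dims=(2,), families=("LDA", "RF"),
                           rf_n_trees=(20,))
        a = grid_search(ds, grid, ScoringParams(k_folds=5), seed=7)
        b = grid_search(ds, grid, ScoringParams(k_folds=5), seed=7)
        assert a.table.equals(b.table)
        assert a.winner == b.winner

    def test_leakage_hook_sees_disjoint_folds(self, rng):
        ds = _toy_dataset(rng)
        seen = []

        def hook(tr, va):
            assert len(np.intersect1d(tr, va)) == 0
            assert len(tr) + len(va) == ds.n_samples
            seen.append((tr.copy(), va.copy()))

        grid = [GridPoint("pca", 2, ClassifierSpec("LDA", reg=0.0))]
        grid_search(ds, grid, ScoringParams(k_folds=5), seed=0, leakage_hook=hook)
        assert len(seen) == 5
        all_val = np.sort(np.concatenate([va for _, va in seen]))
        np.testing.assert_array_equal(all_val, np.arange(ds.n_samples))

    def test_rf_tree_sharing_matches_direct_fits(self, rng):
        # the shared-forest fast path must give identical fold metrics to
        # fitting each n_trees forest independently
        from sersml import classifiers
        from sersml.selection import stratified_kfold as skf

        ds = _toy_dataset(rng, n0=25, n1=25)
        spec_small = ClassifierSpec("RF", n_trees=15, min_samples_split=2,
                                    min_samples_leaf=1, max_features="sqrt")
        spec_big = ClassifierSpec("RF", n_trees=40, min_samples_split=2,
                                  min_samples_leaf=1, max_features="sqrt")
        grid = [GridPoint(None, None, spec_small), GridPoint(None, None, spec_big)]
        res = grid_search(ds, grid, ScoringParams(k_folds=5), seed=11)
        assert not res.table["failed"].any()

        # independently refit the winner per fold and require identical
        # fold-score vectors to the shared-forest result
        folds = skf(ds.labels, 5, seed=11)
        all_idx = np.arange(ds.n_samples)
        direct = []
        win_spec = res.winner.spec
        for va in folds:
            tr = np.setdiff1d(all_idx, va)
            model = classifiers.fit(win_spec, ds.matrix[tr], ds.labels[tr], seed=11)
            direct.append(wba(ds.labels[va], classifiers.predict(model, ds.matrix[va])))
        np.testing.assert_allclose(res.winner_scores.wba_per_fold, direct)
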