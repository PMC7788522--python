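import itertools

import numpy as np
import pytest

from medsup import (
    LabeledTable,
    balance,
    classification_rate,
    confusion_matrix,
    her2_like_pair,
    independent_test,
    kfold_cv,
    mann_whitney,
    sensitivity,
)


def mw_enumeration(a, b):
    """Independent oracle: enumerate all C(n_a + n_b, n_a) equally likely
    assignments of the pooled values to group a, count U = #{pairs a > b},
    and take the two-sided tail probability of the observed U."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def ustat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = ustat(a, b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n_a):
        left = [pooled[i] for i in comb]
        right = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(ustat(left, right))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestClassificationRate:
    def test_simple_ratio(self):
        pred = ["A"] * 9 + ["B"]
        truth = ["A"] * 10
        assert classification_rate(pred, truth) == 0.90

    @pytest.mark.parametrize(
        "matrix,expected",
        [
            # diagonal sum over total for the two printed error matrices
            (np.array([[51, 8], [0, 3]]), 54 / 62),
            (np.array([[47, 10], [4, 1]]), 48 / 62),
        ],
    )
    def test_matches_confusion_diagonal(self, matrix, expected):
        levels = ("Negative", "Positive")
        pred, truth = [], []
        for i, j in itertools.product(range(2), range(2)):
            pred += [levels[i]] * matrix[i, j]
            truth += [levels[j]] * matrix[i, j]
        assert classification_rate(pred, truth) == pytest.approx(expected)
        cm = confusion_matrix(pred, truth, levels)
        assert np.array_equal(cm.counts, matrix)
        assert cm.rate() == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            classification_rate(["A"], ["A", "B"])
        with pytest.raises(ValueError):
            classification_rate([], [])


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        pred = truth = ["A"] * 5 + ["B"] * 5
        cm = confusion_matrix(pred, truth, ("A", "B"))
        assert np.array_equal(cm.counts, [[5, 0], [0, 5]])

    def test_rows_are_predicted_columns_truth(self):
        pred = ["A"] * 5
        truth = ["A", "A", "A", "B", "B"]
        cm = confusion_matrix(pred, truth, ("A", "B"))
        assert np.array_equal(cm.counts, [[3, 2], [0, 0]])

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        pred = rng.choice(["A", "B"], 37)
        truth = rng.choice(["A", "B"], 37)
        assert confusion_matrix(pred, truth, ("A", "B")).total == 37

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(["C"], ["A"], ("A", "B"))


class TestIndependentTest:
    def test_ms_on_balanced_data_equals_plain(self):
        rng = np.random.default_rng(1)
        t = LabeledTable(
            ["x", "y"], rng.normal(5, 2, (30, 2)), ["A"] * 15 + ["B"] * 15
        )
        test = LabeledTable(["x", "y"], rng.normal(5, 2, (12, 2)), ["A"] * 6 + ["B"] * 6)
        for ms, plain in [("MSRandomForest", "RandomForest"), ("MSNaiveBayes", "NaiveBayes")]:
            a = independent_test(t, test, ms, seed=3, n_trees=20)
            b = independent_test(t, test, plain, seed=3, n_trees=20)
            assert list(a.predictions) == list(b.predictions)

    def test_her2_like_report_shape(self):
        train, test = her2_like_pair(2)
        rep = independent_test(train, test, "MSNaiveBayes", seed=2)
        assert rep.confusion.total == 62
        assert rep.confusion.counts.shape == (2, 2)
        assert 0.0 <= rep.rate <= 1.0
        assert len(rep.predictions) == 62

    def test_seed_reproducibility(self):
        train, test = her2_like_pair(3)
        a = independent_test(train, test, "MSRandomForest", seed=5, n_trees=30)
        b = independent_test(train, test, "MSRandomForest", seed=5, n_trees=30)
        assert list(a.predictions) == list(b.predictions)
        assert a.rate == b.rate

    def test_unknown_method(self):
        train, test = her2_like_pair(4)
        with pytest.raises(ValueError, match="unknown method"):
            independent_test(train, test, "GradientBoost", seed=0)


class TestKFoldCV:
    def test_fold_arithmetic(self):
        train, _ = her2_like_pair(5)
        rs = kfold_cv(train, "MSNaiveBayes", k=10, repeats=3, seed=1)
        assert rs.rates.shape == (30,)
        assert ((rs.rates >= 0) & (rs.rates <= 1)).all()

    def test_stratified_folds_hold_out_each_row_once(self):
        train, _ = her2_like_pair(6)
        rs = kfold_cv(
            train, "NaiveBayes", k=10, repeats=1, seed=2, collect_folds=True
        )
        held_out = np.concatenate([r["test_indices"] for r in rs.fold_records])
        assert sorted(held_out) == list(range(100))
        # stratification: every fold sees at least one minority instance
        for r in rs.fold_records:
            assert (train.labels[r["test_indices"]] == "Positive").sum() >= 1

    def test_no_synthetic_leakage_into_held_out_folds(self):
        train, _ = her2_like_pair(7)
        rs = kfold_cv(
            train, "MSNaiveBayes", k=10, repeats=2, seed=3, collect_folds=True
        )
        for r in rs.fold_records:
            bal = r["balanced_train"]
            assert bal is not None and bal.is_synthetic.sum() > 0
            # held-out rows come from the original table...
            np.testing.assert_array_equal(
                r["truth"], train.labels[r["test_indices"]]
            )
            # ...and the training split recovers exactly the complement
            train_idx = np.setdiff1d(np.arange(100), r["test_indices"])
            orig = bal.original()
            np.testing.assert_array_equal(orig.values, train.values[train_idx])

    def test_class_smaller_than_k_rejected(self):
        t = LabeledTable(
            ["x"], np.arange(12, dtype=float)[:, None], ["A"] * 9 + ["B"] * 3
        )
        with pytest.raises(ValueError, match="fewer than k"):
            kfold_cv(t, "NaiveBayes", k=5, repeats=1, seed=0)

    def test_perfectly_separable_rates_are_one(self):
        values = np.concatenate([np.arange(20.0), np.arange(100.0, 120.0)])[:, None]
        t = LabeledTable(["x"], values, ["A"] * 20 + ["B"] * 20)
        rs = kfold_cv(t, "MSNaiveBayes", k=4, repeats=2, seed=4)
        assert (rs.rates == 1.0).all()


class TestMannWhitney:
    def test_textbook_extreme_case(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.10)

    def test_identical_samples(self):
        a = [0.5, 0.6, 0.7, 0.8] * 3
        u, p = mann_whitney(a, a)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 5)
        u1, p1 = mann_whitney(a, b)
        u2, p2 = mann_whitney(b, a)
        assert p1 == pytest.approx(p2)
        assert u2 == pytest.approx(len(a) * len(b) - u1)

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for n_a, n_b in [(2, 3), (3, 3), (4, 2), (5, 5)]:
            a = rng.normal(0, 1, n_a)
            b = rng.normal(0.8, 1, n_b)
            u, p = mann_whitney(a, b)
            u_ref, p_ref = mw_enumeration(a, b)
            assert u == u_ref
            assert p == pytest.approx(p_ref)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSensitivity:
    def test_minority_recall(self):
        pred = ["Neg", "Neg", "Pos", "Pos"]
        truth = ["Neg", "Pos", "Pos", "Pos"]
        assert sensitivity(pred, truth, "Pos") == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            sensitivity(pred, truth, "Other")
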