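"""Train/validation splitting, classifiers, confusion matrices, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import idcpheno as ip
from idcpheno.benchmarks import dirichlet_feature_dataset
from idcpheno.scoring import (
    FEATURES,
    NeuralNetClassifier,
    adjacent_misclassification_fraction,
    confusion_from_predictions,
)


def _separable(n=200, seed=0):
    """prop_brown > 0.5 <=> class 5; otherwise class 1."""
    rng = np.random.default_rng(seed)
    brown = np.concatenate([rng.uniform(0.6, 0.9, n // 2),
                            rng.uniform(0.0, 0.4, n - n // 2)])
    green = (1 - brown) * 0.8
    yellow = 1 - brown - green
    return pd.DataFrame({
        "prop_green": green, "prop_yellow": yellow, "prop_brown": brown,
        "score": np.where(brown > 0.5, 5, 1),
    })


class TestSplit:
    def test_validation_size(self):
        data = dirichlet_feature_dataset(300, seed=1)
        out = ip.split_train_validation(data, 0.33, seed=2)
        n_val = (out["partition"] == "validation").sum()
        assert abs(n_val - 99) <= 5  # stratification rounding

    def test_same_seed_identical(self):
        data = dirichlet_feature_dataset(120, seed=1)
        a = ip.split_train_validation(data, seed=3)
        b = ip.split_train_validation(data, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_stratified_per_class_share(self):
        data = dirichlet_feature_dataset(500, seed=4)
        out = ip.split_train_validation(data, 0.33, seed=5)
        for _, grp in out.groupby("score"):
            n_val = (grp["partition"] == "validation").sum()
            assert abs(n_val - 0.33 * len(grp)) <= 1

    def test_partitions_disjoint_exhaustive(self):
        data = dirichlet_feature_dataset(100, seed=6)
        out = ip.split_train_validation(data, seed=7)
        assert set(out["partition"]) == {"train", "validation"}

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ip.split_train_validation(dirichlet_feature_dataset(50), 1.5)


class TestRandomForest:
    def test_separable_rule_learned_perfectly(self):
        train, test = _separable(seed=0), _separable(seed=1)
        clf = ip.train_random_forest(train, seed=0)
        assert ip.evaluate(clf, test).overall_accuracy == 100.0

    def test_row_order_invariance_after_canonical_sort(self):
        data = dirichlet_feature_dataset(300, seed=2)
        shuffled = data.sample(frac=1.0, random_state=9)
        canon = data.sort_values(FEATURES).reset_index(drop=True)
        canon2 = shuffled.sort_values(FEATURES).reset_index(drop=True)
        p1 = ip.train_random_forest(canon, seed=1).predict(data[FEATURES].to_numpy())
        p2 = ip.train_random_forest(canon2, seed=1).predict(data[FEATURES].to_numpy())
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        df = _separable()
        with pytest.raises(ValueError, match="2 score classes"):
            ip.train_random_forest(df[df["score"] == 1])


class TestNeuralNetwork:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        data = _separable(60, seed=3)
        X = data[FEATURES].to_numpy()
        y = data["score"].to_numpy()
        ref = NeuralNetClassifier(learning_rate=0.0, max_epochs=50, seed=4)
        # reproduce the initial weights by drawing with the same generator
        rng = np.random.default_rng(4)
        n_hold = int(round(len(X) * ref.holdout_fraction))
        rng.permutation(len(X))
        W1_init = rng.normal(0.0, 0.5, size=(3, 3))
        ref.fit(X, y)
        np.testing.assert_allclose(ref.W1_, W1_init)

    def test_linearly_separable_two_class_reaches_100(self):
        data = _separable(200, seed=5)
        clf = ip.train_neural_network(data, seed=5)
        acc = (clf.predict(data[FEATURES].to_numpy()) == data["score"]).mean()
        assert acc == 1.0

    def test_deterministic_under_seed(self):
        data = dirichlet_feature_dataset(200, seed=6)
        p1 = ip.train_neural_network(data, seed=2).predict(data[FEATURES].to_numpy())
        p2 = ip.train_neural_network(data, seed=2).predict(data[FEATURES].to_numpy())
        np.testing.assert_array_equal(p1, p2)


class TestConfusion:
    def test_perfect_predictions_identity_pattern(self):
        y = np.array([1, 2, 3, 4, 5] * 4)
        cm = confusion_from_predictions(y, y)
        assert cm.overall_accuracy == 100.0
        assert np.all(np.diag(cm.counts.to_numpy()) == 4)

    def test_two_class_diagonal_arithmetic(self):
        # 469 + 487 correct of 1000 -> 95.6%
        y_true = np.array([1] * 500 + [2] * 500)
        y_pred = np.array([1] * 469 + [2] * 31 + [1] * 13 + [2] * 487)
        cm = confusion_from_predictions(y_true, y_pred, classes=(1, 2))
        assert cm.overall_accuracy == pytest.approx(95.6)

    def test_row_sums_and_percentages(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(1, 6, 200)
        y_pred = rng.integers(1, 6, 200)
        cm = confusion_from_predictions(y_true, y_pred)
        ref_counts = pd.Series(y_true).value_counts()
        for cls in range(1, 6):
            assert cm.counts.loc[cls].sum() == ref_counts.get(cls, 0)
        sums = cm.row_percent.sum(axis=1).dropna()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(2)
        n = 5000
        y_true = rng.integers(1, 6, n)
        y_pred = rng.integers(1, 6, n)
        cm = confusion_from_predictions(y_true, y_pred)
        se = 100 * np.sqrt(0.2 * 0.8 / n)
        assert cm.overall_accuracy == pytest.approx(20.0, abs=4 * se)


class TestBinning:
    def test_score_bin_definition(self):
        np.testing.assert_array_equal(
            ip.bin_scores([1, 2, 3, 4, 5]), ["low", "low", "low", "high", "high"]
        )

    def test_within_bin_errors_count_correct(self):
        acc, _ = ip.binned_accuracy([2, 4], [3, 5])
        assert acc == 100.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)),
                    min_size=1, max_size=60))
    def test_binned_accuracy_never_below_five_class(self, pairs):
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        acc5 = 100.0 * np.mean(np.array(y_true) == np.array(y_pred))
        acc2, _ = ip.binned_accuracy(y_true, y_pred)
        assert acc2 >= acc5 - 1e-12

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            ip.bin_scores([0, 3])


def test_adjacent_fraction_arithmetic():
    # 10 errors at distance 1, 5 at distance 2 -> fraction 2/3
    y_true = np.array([2] * 15 + [1] * 10)
    y_pred = np.array([3] * 10 + [4] * 5 + [1] * 10)
    cm = confusion_from_predictions(y_true, y_pred)
    assert adjacent_misclassification_fraction(cm) == pytest.approx(10 / 15)
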