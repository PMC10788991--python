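"""Stratified folds, class weights, metrics, and cross-validation plumbing."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from nyhagrade.train_eval import (
    ConfusionMatrix,
    MetricsReport,
    TrainConfig,
    class_weights,
    compute_metrics,
    stratified_kfold,
    train_cv,
)


class TestStratifiedKFold:
    def test_balanced_100_labels_give_5_per_class_per_fold(self):
        labels = np.repeat([1, 2, 3, 4], 25)
        folds = stratified_kfold(labels, k=5, seed=0)
        assert len(folds) == 5
        for fold in folds:
            values, counts = np.unique(labels[fold], return_counts=True)
            assert list(values) == [1, 2, 3, 4]
            assert list(counts) == [5, 5, 5, 5]

    def test_partition_covers_everything_disjointly(self, rng):
        labels = rng.integers(1, 5, size=103)
        folds = stratified_kfold(labels, k=5, seed=1)
        union = np.concatenate(folds)
        assert sorted(union) == list(range(103))
        assert len(union) == len(set(union))

    def test_fold_histograms_match_proportional_allocation(self, rng):
        labels = np.repeat([1, 2, 3, 4], [8, 47, 115, 98])
        rng.shuffle(labels)
        folds = stratified_kfold(labels, k=4, seed=2)
        _, global_counts = np.unique(labels, return_counts=True)
        for fold in folds:
            _, counts = np.unique(labels[fold], return_counts=True)
            # each fold's class count is within 1 of the exact share
            np.testing.assert_allclose(counts, global_counts / 4, atol=1.0)

    def test_deterministic_for_fixed_seed(self, rng):
        labels = rng.integers(1, 5, size=60)
        a = stratified_kfold(labels, k=3, seed=9)
        b = stratified_kfold(labels, k=3, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_small_class_error_names_class(self):
        labels = np.array([1] * 20 + [2] * 3)
        with pytest.raises(ValueError, match="class 2"):
            stratified_kfold(labels, k=5)

    def test_group_aware_split_keeps_groups_whole(self):
        labels = np.repeat([1, 2, 3, 4], 20)
        groups = np.repeat(np.arange(40), 2)  # two segments per subject
        folds = stratified_kfold(labels, k=5, seed=0, groups=groups)
        seen = {}
        for i, fold in enumerate(folds):
            for g in groups[fold]:
                assert seen.setdefault(g, i) == i


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = class_weights(np.repeat([1, 2, 3, 4], 10))
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_cohort_counts_inverse_frequency(self):
        counts = (8, 47, 115, 98)
        labels = np.repeat([1, 2, 3, 4], counts)
        w = class_weights(labels)
        n, k = sum(counts), 4
        for c, nc in zip([1, 2, 3, 4], counts):
            assert w[c] == pytest.approx(n / (k * nc))
        # proportional to inverse counts
        ratios = [w[c] * nc for c, nc in zip([1, 2, 3, 4], counts)]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="at least 2 classes"):
            class_weights(np.ones(10))


class TestComputeMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7, 8]), classes=(1, 2, 3, 4))
        report = compute_metrics(cm)
        for c in (1, 2, 3, 4):
            for m in ("acc", "ppv", "sen", "spe"):
                assert report.per_class[c][m] == pytest.approx(100.0)
        assert report.overall_accuracy == pytest.approx(100.0)

    def test_two_class_hand_count(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), classes=(1, 2))
        r = compute_metrics(cm)
        assert r.per_class[1]["sen"] == pytest.approx(80.0)
        assert r.per_class[1]["ppv"] == pytest.approx(8 / 9 * 100)
        assert r.per_class[1]["spe"] == pytest.approx(90.0)
        assert r.per_class[1]["acc"] == pytest.approx(85.0)

    def test_matches_brute_force_counting(self, rng):
        y_true = rng.integers(1, 5, size=400)
        y_pred = np.where(rng.random(400) < 0.7, y_true, rng.integers(1, 5, size=400))
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes=(1, 2, 3, 4))
        report = compute_metrics(cm)
        for c in (1, 2, 3, 4):
            tp = int(np.sum((y_true == c) & (y_pred == c)))
            fp = int(np.sum((y_true != c) & (y_pred == c)))
            tn = int(np.sum((y_true != c) & (y_pred != c)))
            fn = int(np.sum((y_true == c) & (y_pred != c)))
            assert report.per_class[c]["acc"] == pytest.approx(
                100 * (tp + tn) / len(y_true))
            if tp + fp:
                assert report.per_class[c]["ppv"] == pytest.approx(100 * tp / (tp + fp))
            assert report.per_class[c]["sen"] == pytest.approx(100 * tp / (tp + fn))
            assert report.per_class[c]["spe"] == pytest.approx(100 * tn / (tn + fp))
        assert report.macro["sen"] == pytest.approx(
            np.mean([report.per_class[c]["sen"] for c in (1, 2, 3, 4)]))

    def test_undefined_ppv_excluded_with_warning(self):
        counts = np.array([[5, 0, 0, 0], [5, 0, 0, 0], [0, 0, 3, 2], [0, 0, 1, 4]])
        cm = ConfusionMatrix(counts, classes=(1, 2, 3, 4))
        with pytest.warns(UserWarning, match="PPV undefined"):
            report = compute_metrics(cm)
        assert report.per_class[2]["ppv"] is None
        defined = [report.per_class[c]["ppv"] for c in (1, 3, 4)]
        assert report.macro["ppv"] == pytest.approx(np.mean(defined))

    def test_accuracy_invariant_under_class_permutation(self, rng):
        counts = rng.integers(0, 30, size=(4, 4))
        cm = ConfusionMatrix(counts, classes=(1, 2, 3, 4))
        perm = rng.permutation(4)
        cm_p = ConfusionMatrix(counts[np.ix_(perm, perm)], classes=(1, 2, 3, 4))
        assert compute_metrics(cm).overall_accuracy == pytest.approx(
            compute_metrics(cm_p).overall_accuracy)

    def test_row_sums_equal_tp_plus_fn(self, rng):
        counts = rng.integers(0, 20, size=(4, 4)) + 1
        cm = ConfusionMatrix(counts, classes=(1, 2, 3, 4))
        for i in range(4):
            tp, fp, tn, fn = cm.one_vs_rest(i)
            assert tp + fn == counts[i].sum()
            assert tp + fp + tn + fn == cm.total


class _MajorityOracle(BaseEstimator, ClassifierMixin):
    """Constant-output classifier: always predicts its constant class."""

    def __init__(self, constant=1):
        self.constant = constant

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.full(len(X), self.constant)


class TestTrainCV:
    def test_constant_model_accuracy_equals_class_share(self, rng):
        X = rng.normal(size=(200, 30))
        y = np.repeat([1, 2, 3, 4], [20, 60, 80, 40])
        result = train_cv(X, y, estimator=_MajorityOracle(constant=3), k=5, seed=0)
        for fold in result.folds:
            share = np.mean(y[fold.test_indices] == 3)
            assert fold.report.overall_accuracy == pytest.approx(100 * share)

    def test_five_folds_of_200_on_1000_segments(self, rng):
        X = rng.normal(size=(1000, 10))
        y = np.tile([1, 2, 3, 4], 250)
        result = train_cv(X, y, estimator=_MajorityOracle(), k=5, seed=1)
        assert len(result.folds) == 5
        for fold in result.folds:
            assert fold.confusion.total == 200

    def test_average_equals_mean_of_folds(self, rng):
        X = rng.normal(size=(120, 10))
        y = np.tile([1, 2, 3, 4], 30)
        result = train_cv(X, y, estimator=_MajorityOracle(constant=2), k=5, seed=2)
        fold_accs = [f.report.overall_accuracy for f in result.folds]
        assert result.averaged.overall_accuracy == pytest.approx(
            np.mean(fold_accs), abs=1e-12)
        fold_sens = [f.report.macro["sen"] for f in result.folds]
        assert result.averaged.macro["sen"] == pytest.approx(np.mean(fold_sens))

    def test_confusion_totals_match_held_out_sizes(self, rng):
        X = rng.normal(size=(101, 5))
        y = rng.integers(1, 5, size=101)
        result = train_cv(X, y, estimator=_MajorityOracle(), k=4, seed=3)
        assert sum(f.confusion.total for f in result.folds) == 101


class TestTrainConfig:
    def test_defaults_follow_study_settings(self):
        cfg = TrainConfig()
        assert (cfg.learning_rate, cfg.epochs, cfg.batch_size, cfg.folds) == (
            0.001, 60, 32, 5)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
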