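"""Splits, forests, imbalance resampling, metrics, protocol comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from cpqsar.conformal import ConformalResult
from cpqsar.protocols import (
    MetricsReport,
    SplitPlan,
    evaluate,
    evaluate_binary,
    evaluate_conformal,
    metrics_from_confusion,
    resample,
    run_cp_protocol,
    split_stratified,
    train_forest,
)
from cpqsar.synthetic import GeneratorConfig, make_endpoint_dataset

from conftest import make_labeled_dataset


class TestSplitStratified:
    y = np.concatenate([np.ones(10, int), np.zeros(90, int)])
    plan = SplitPlan(seed=5)

    def test_each_test_fold_preserves_the_class_ratio(self):
        folds = split_stratified(self.y, self.plan)
        for _, _, test in folds:
            assert test.size == 20
            assert self.y[test].sum() == 2

    def test_same_seed_reproduces_the_split(self):
        a = split_stratified(self.y, self.plan)
        b = split_stratified(self.y, self.plan)
        for (t1, c1, s1), (t2, c2, s2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(c1, c2)
            np.testing.assert_array_equal(s1, s2)

    def test_test_sets_partition_the_data(self):
        folds = split_stratified(self.y, self.plan)
        all_test = np.concatenate([test for _, _, test in folds])
        np.testing.assert_array_equal(np.sort(all_test), np.arange(100))

    def test_parts_are_disjoint_and_stratified_within_fold(self):
        full_ratio = self.y.mean()
        for train, calib, test in split_stratified(self.y, self.plan):
            assert not (set(train) & set(calib))
            assert not (set(train) & set(test))
            for part in (train, calib, test):
                assert abs(self.y[part].mean() - full_ratio) <= 1 / part.size

    def test_class_too_small_to_stratify_raises(self):
        y = np.concatenate([np.ones(3, int), np.zeros(50, int)])
        with pytest.raises(ValueError, match="class 1"):
            split_stratified(y, self.plan)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitPlan(train_frac=0.7, calib_frac=0.2, test_frac=0.2)


class TestTrainForest:
    def test_separable_classes_give_high_test_auc(self):
        ds = make_endpoint_dataset(
            GeneratorConfig(n_compounds=600, active_fraction=0.5,
                            separation=4.0, seed=8)
        )
        forest = train_forest(ds.X[:400], ds.y[:400], seed=8)
        prob = forest.predict_proba(ds.X[400:])[:, 1]
        rep = evaluate_binary(ds.y[400:], (prob >= 0.5).astype(int), prob)
        assert rep.auc > 0.95

    def test_seeded_training_is_deterministic(self):
        ds = make_endpoint_dataset(
            GeneratorConfig(n_compounds=200, active_fraction=0.3, seed=9)
        )
        p1 = train_forest(ds.X, ds.y, seed=1).predict_proba(ds.X)
        p2 = train_forest(ds.X, ds.y, seed=1).predict_proba(ds.X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0)

    def test_single_class_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_forest(np.zeros((10, 2)), np.zeros(10, int))


class TestResample:
    @pytest.fixture()
    def imbalanced(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(100, 4))
        y = np.concatenate([np.ones(10, int), np.zeros(90, int)])
        return X, y

    def test_undersample_matches_classes_exactly(self, imbalanced):
        X, y = imbalanced
        Xr, yr = resample(X, y, "undersample", seed=0)
        assert (yr == 1).sum() == (yr == 0).sum() == 10

    def test_oversample_extras_are_copies_of_minority_rows(self, imbalanced):
        X, y = imbalanced
        Xr, yr = resample(X, y, "oversample_dup", seed=0)
        assert (yr == 1).sum() == (yr == 0).sum() == 90
        np.testing.assert_array_equal(Xr[:100], X)  # originals untouched
        minority_rows = {tuple(row) for row in X[y == 1]}
        for row in Xr[100:]:
            assert tuple(row) in minority_rows

    def test_smote_points_lie_in_the_minority_bounding_box(self, imbalanced):
        X, y = imbalanced
        Xr, yr = resample(X, y, "smote", seed=0)
        assert (yr == 1).sum() == (yr == 0).sum() == 90
        lo = X[y == 1].min(axis=0) - 1e-12
        hi = X[y == 1].max(axis=0) + 1e-12
        synthetic = Xr[100:]
        assert np.all(synthetic >= lo) and np.all(synthetic <= hi)

    def test_smote_needs_enough_minority_neighbours(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = np.concatenate([np.ones(4, int), np.zeros(46, int)])
        with pytest.raises(ValueError, match="SMOTE"):
            resample(X, y, "smote")

    def test_rose_doubles_and_balances_keeping_originals(self, imbalanced):
        X, y = imbalanced
        Xr, yr = resample(X, y, "rose", seed=0)
        assert len(yr) == 200
        assert (yr == 1).sum() == (yr == 0).sum() == 100
        np.testing.assert_array_equal(Xr[:100], X)

    def test_naive_is_identity_and_unknown_protocol_rejected(self, imbalanced):
        X, y = imbalanced
        Xr, yr = resample(X, y, "naive")
        np.testing.assert_array_equal(Xr, X)
        with pytest.raises(ValueError):
            resample(X, y, "bogus")


class TestMetrics:
    def test_hand_computed_confusion_panel(self):
        m = metrics_from_confusion(tp=3, fn=1, fp=2, tn=4)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["mcc"] == pytest.approx(0.40825, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_perfect_predictions(self):
        rep = evaluate_binary([1, 1, 0, 0], [1, 1, 0, 0])
        assert rep.mcc == pytest.approx(1.0)
        assert rep.balanced_accuracy == pytest.approx(1.0)

    def test_degenerate_confusion_reports_missing_not_nan(self):
        rep = evaluate_binary([1, 1], [1, 1])
        assert rep.specificity is None
        assert rep.mcc is None

    def test_matches_sklearn_oracle_on_random_confusions(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            y_true = np.array([1] * (tp + fn) + [0] * (fp + tn))
            y_pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
            m = metrics_from_confusion(tp, fn, fp, tn)
            assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
            assert m["sensitivity"] == pytest.approx(
                recall_score(y_true, y_pred))
            assert m["specificity"] == pytest.approx(
                recall_score(y_true, y_pred, pos_label=0))
            assert m["balanced_accuracy"] == pytest.approx(
                balanced_accuracy_score(y_true, y_pred))
            assert m["mcc"] == pytest.approx(
                matthews_corrcoef(y_true, y_pred))
            # balanced PPV/NPV: the PPV/NPV sklearn reports when each
            # true class is reweighted to equal mass.
            w = np.where(y_true == 1, 1.0 / (tp + fn), 1.0 / (fp + tn))
            assert m["balanced_ppv"] == pytest.approx(
                precision_score(y_true, y_pred, sample_weight=w))
            assert m["balanced_npv"] == pytest.approx(
                precision_score(y_true, y_pred, pos_label=0, sample_weight=w))

    def test_conformal_coverage_counts_single_labels(self):
        results = (
            [ConformalResult(0.9, 0.1)] * 5      # active
            + [ConformalResult(0.1, 0.9)] * 3    # inactive
            + [ConformalResult(0.9, 0.9)]        # both
            + [ConformalResult(0.05, 0.05)]      # empty
        )
        y = [1] * 5 + [0] * 5
        rep = evaluate(results, y, epsilon=0.2)
        assert rep.coverage == pytest.approx(0.8)
        full = evaluate_conformal(results, y, 0.2, include_unclassified=True)
        assert full.coverage == 1.0

    def test_report_schema_for_classical_protocols_has_no_validity(self):
        rep = evaluate([1, 0, 1], [1, 0, 0])
        assert isinstance(rep, MetricsReport)
        assert rep.validity_active is None and rep.epsilon is None


class TestProtocolComparison:
    def test_imbalance_pattern_on_skewed_data(self, imbalance_comparison):
        table = imbalance_comparison
        naive, under = table.loc["naive"], table.loc["undersample"]
        assert naive["sensitivity"] < under["sensitivity"]
        assert naive["specificity"] > 0.9
        assert naive["specificity"] > naive["sensitivity"]

    def test_undersampling_balances_the_two_error_rates(
        self, imbalance_comparison
    ):
        under = imbalance_comparison.loc["undersample"]
        assert abs(under["sensitivity"] - under["specificity"]) < 0.2

    def test_cp_run_is_bit_reproducible(self, quick_cp_run):
        dataset, run = quick_cp_run
        rerun = run_cp_protocol(dataset, n_iterations=3, n_trees=50, seed=3)
        np.testing.assert_array_equal(run.p1, rerun.p1)
        np.testing.assert_array_equal(run.p0, rerun.p0)

    def test_cp_pooled_pvalues_cover_every_compound(self, quick_cp_run):
        _, run = quick_cp_run
        assert np.all(np.isfinite(run.p1)) and np.all(np.isfinite(run.p0))
        assert run.p1.min() > 0 and run.p1.max() <= 1

    def test_endpoint_model_roundtrip(self, quick_cp_run, tmp_path):
        dataset, run = quick_cp_run
        run.model.save(tmp_path / "model.joblib")
        from cpqsar.protocols import EndpointModel
        back = EndpointModel.load(tmp_path / "model.joblib")
        p1a, p0a = run.model.predict_p(dataset.X[:20])
        p1b, p0b = back.predict_p(dataset.X[:20])
        np.testing.assert_array_equal(p1a, p1b)
        np.testing.assert_array_equal(p0a, p0b)
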