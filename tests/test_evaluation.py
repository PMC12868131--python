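"""Confusion metrics, AUC, cross-validation and comparison harnesses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mhcview.data_io import make_cv_folds_from_labels
from mhcview.deep_model import NetConfig
from mhcview.evaluation import (
    CLASSIFIER_NAMES,
    ConfusionCounts,
    ablation_suite,
    compare_classifiers,
    compute_metrics,
    confusion_counts,
    cross_validate,
    roc_auc,
)


class TestConfusionCounts:
    def test_perfect_agreement(self):
        c = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_mixed_case(self):
        c = confusion_counts([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 1)

    def test_loop_oracle_on_random_pairs(self, rng):
        y = rng.integers(0, 2, 500)
        p = rng.integers(0, 2, 500)
        c = confusion_counts(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        assert c.total == 500

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_counts([1, 2], [1, 0])


class TestComputeMetrics:
    def test_worked_case(self):
        m = compute_metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
        assert m.ACC == pytest.approx(0.9)
        assert m.SP == pytest.approx(0.8)
        assert m.SN == pytest.approx(1.0)
        assert m.MCC == pytest.approx(2000 / np.sqrt(60 * 50 * 50 * 40), abs=1e-9)
        assert m.MCC == pytest.approx(0.8165, abs=5e-5)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(30, 30, 0, 0))
        assert m.ACC == 1.0 and m.MCC == 1.0

    def test_all_positive_predictor_gets_zero_mcc(self):
        m = compute_metrics(ConfusionCounts(TP=50, TN=0, FP=50, FN=0))
        assert m.MCC == 0.0
        assert m.SP == 0.0 and m.SN == 1.0

    def test_absent_class_reports_none_not_zero(self):
        m = compute_metrics(ConfusionCounts(TP=5, TN=0, FP=0, FN=0))
        assert m.SP is None and m.SN == 1.0

    def test_exhaustive_small_tables_against_oracle(self):
        """All tables with entries <= 6 match naive formula evaluation."""
        for tp, tn, fp, fn in itertools.product(range(7), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            total = tp + tn + fp + fn
            assert m.ACC == pytest.approx((tp + tn) / total)
            if tn + fp:
                assert m.SP == pytest.approx(tn / (tn + fp))
            if tp + fn:
                assert m.SN == pytest.approx(tp / (tp + fn))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected_mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
            assert m.MCC == pytest.approx(expected_mcc, abs=1e-12)

    def test_mcc_symmetry_and_negation(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 20, 4)
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            swapped = compute_metrics(  # swap labels <-> predictions: FP <-> FN
                ConfusionCounts(int(tp), int(tn), int(fn), int(fp)))
            assert m.MCC == pytest.approx(swapped.MCC, abs=1e-12)
            flipped = compute_metrics(  # flip all predictions
                ConfusionCounts(int(fn), int(fp), int(tn), int(tp)))
            assert flipped.MCC == pytest.approx(-m.MCC, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_pairwise_comparison_oracle(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = np.round(rng.random(200), 2)  # coarse scores force ties
        pos = s[y == 1]
        neg = s[y == 0]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        assert roc_auc(y, s) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.random(100)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(3 * s)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.2, 0.8])


def _toy_features(rng, n=100, dim=8, separation=4.0):
    y = np.array([i % 2 for i in range(n)])
    direction = np.ones(dim) / np.sqrt(dim)
    X = rng.standard_normal((n, dim)) + (y * 2 - 1)[:, None] * separation / 2 * direction
    frame = pd.DataFrame(X, index=[f"r{i}" for i in range(n)])
    labels = pd.Series(y, index=frame.index)
    return frame, labels


class TestCrossValidate:
    class _AlwaysPositive:
        def fit(self, X, y):
            return self

        def predict_proba(self, X):
            return np.column_stack([np.zeros(len(X)), np.ones(len(X))])

    def test_constant_model_on_balanced_data(self, rng):
        frame, labels = _toy_features(rng)
        plan = make_cv_folds_from_labels(labels.to_dict(), n_folds=5, seed=0)
        table = cross_validate(frame, labels, plan, lambda fold: self._AlwaysPositive())
        assert table.loc["mean", "ACC"] == pytest.approx(0.5)
        assert table.loc["mean", "SN"] == pytest.approx(1.0)
        assert table.loc["mean", "SP"] == pytest.approx(0.0)

    def test_per_fold_rows_match_aggregate(self, rng):
        frame, labels = _toy_features(rng)
        plan = make_cv_folds_from_labels(labels.to_dict(), n_folds=5, seed=0)
        from sklearn.linear_model import LogisticRegression
        table = cross_validate(frame, labels, plan,
                               lambda fold: LogisticRegression(max_iter=500))
        folds = table.drop(index=["mean", "sd"])
        assert table.loc["mean", "ACC"] == pytest.approx(folds["ACC"].mean())
        assert len(folds) == 5

    def test_separable_task_high_accuracy(self, rng):
        frame, labels = _toy_features(rng, n=200, separation=6.0)
        plan = make_cv_folds_from_labels(labels.to_dict(), n_folds=5, seed=0)
        from sklearn.linear_model import LogisticRegression
        table = cross_validate(frame, labels, plan,
                               lambda fold: LogisticRegression(max_iter=500))
        assert table.loc["mean", "ACC"] >= 0.95

    def test_plan_coverage_validated(self, rng):
        frame, labels = _toy_features(rng, n=40)
        plan = make_cv_folds_from_labels(labels.iloc[:30].to_dict(), n_folds=3, seed=0)
        with pytest.raises(ValueError, match="cover"):
            cross_validate(frame, labels, plan, lambda fold: self._AlwaysPositive())


class TestCompareClassifiers:
    def test_schema_and_determinism_and_easy_task(self, rng):
        frame, labels = _toy_features(rng, n=120, separation=6.0)
        plan = make_cv_folds_from_labels(labels.to_dict(), n_folds=3, seed=0)
        a = compare_classifiers(frame, labels, plan, seed=0)
        b = compare_classifiers(frame, labels, plan, seed=0)
        assert list(a.index) == list(CLASSIFIER_NAMES)
        assert {"ACC", "SP", "SN", "MCC", "AUC"} <= set(a.columns)
        pd.testing.assert_frame_equal(a, b)
        assert (a["ACC"] > 0.7).all()


class TestAblationSuite:
    def test_four_rows_shared_split_and_v3_consistency(self, rng):
        frame, labels = _toy_features(rng, n=80, dim=16, separation=6.0)
        plan = make_cv_folds_from_labels(labels.to_dict(), n_folds=3, seed=0)
        cfg = NetConfig(input_dim=16, timesteps=4, lstm_hidden=4, attn_dim=8,
                        attn_heads=2, head_hidden=4, max_epochs=8, seed=0)
        table = ablation_suite(frame, labels, plan, cfg)
        assert list(table.index) == ["FULL", "V1_NO_BILSTM", "V2_NO_ATTN",
                                     "V3_HEAD_ONLY"]
        assert table["split_hash"].nunique() == 1
        # V3 row equals running the head-only estimator directly
        from mhcview.evaluation import _DeepEstimator
        direct = cross_validate(frame, labels, plan,
                                lambda fold: _DeepEstimator("V3_HEAD_ONLY", cfg))
        assert table.loc["V3_HEAD_ONLY", "ACC"] == pytest.approx(
            direct.loc["mean", "ACC"])
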