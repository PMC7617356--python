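"""Metric panel, AUC, calibration, CV grid search, repeated test runs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from mosr.cohort import make_fixture
from mosr.evaluation import (CVPlan, ConfusionCounts, calibration_bins,
                             confusion, evaluate_probabilities, grid_search_cv,
                             metric_panel, overfit_gap, repeated_test_eval,
                             roc_auc, stratified_allocation)


class TestConfusion:
    def test_perfect_probabilities(self):
        c = confusion([1, 0, 1], [1.0, 0.0, 1.0])
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 1)

    def test_hand_tally(self):
        c = confusion([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1], 0.5)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_zero_threshold_predicts_all_positive(self):
        c = confusion([1, 0, 0, 0], [0.2, 0.1, 0.3, 0.0], threshold=0.0)
        assert c.fp == 3 and c.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [0.5])


class TestMetricPanel:
    def test_f1_closed_form(self):
        rep = metric_panel(ConfusionCounts(tp=2, fp=1, tn=0, fn=1))
        assert rep.f1 == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))

    def test_perfect_counts(self):
        rep = metric_panel(ConfusionCounts(tp=3, fp=0, tn=5, fn=0))
        for m in ("accuracy", "sensitivity", "specificity", "f1", "ppv", "npv"):
            assert getattr(rep, m) == 1.0

    def test_undefined_marker_policy(self):
        # no positives at all and none predicted: sens/ppv/f1 undefined
        rep = metric_panel(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert rep.sensitivity is None and rep.ppv is None and rep.f1 is None
        # TP = 0 with errors present: F1 takes the conventional 0
        rep = metric_panel(ConfusionCounts(tp=0, fp=1, tn=3, fn=2))
        assert rep.f1 == 0.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            metric_panel(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_reference_implementation(self):
        """Panel matches scikit-learn on hundreds of random confusion tables."""
        rng = np.random.default_rng(23)
        for _ in range(500):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            if len(np.unique(y)) < 2:
                continue
            pred = (p >= 0.5).astype(int)
            rep = metric_panel(confusion(y, p))
            assert rep.accuracy == pytest.approx(accuracy_score(y, pred))
            assert rep.sensitivity == pytest.approx(
                recall_score(y, pred, zero_division=np.nan), nan_ok=True)
            if rep.ppv is not None:
                assert rep.ppv == pytest.approx(
                    precision_score(y, pred, zero_division=np.nan))
            assert (rep.f1 if rep.f1 is not None else np.nan) == pytest.approx(
                f1_score(y, pred, zero_division=np.nan), nan_ok=True)

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            y = rng.integers(0, 2, 30)
            p = rng.random(30)
            rep = metric_panel(confusion(y, p))
            if rep.ppv and rep.sensitivity:
                hm = 2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity)
                assert rep.f1 == pytest.approx(hm)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        assert roc_auc([1, 1, 1], [0.1, 0.5, 0.9]) is None

    def test_pairwise_concordance_oracle(self):
        """AUC equals brute-force concordance with half-credit ties."""
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((1.0 if a > b else 0.5 if a == b else 0.0)
                       for a in pos for b in neg)
            want = conc / (len(pos) * len(neg))
            assert roc_auc(y, s) == pytest.approx(want, abs=1e-12)
            assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))


class TestCalibration:
    def test_single_populated_bin_reports_prevalence(self):
        y = [0, 1, 0, 0, 1]
        p = [0.42, 0.44, 0.41, 0.43, 0.45]
        bins = calibration_bins(y, p, n_bins=10)
        populated = [b for b in bins if b.count]
        assert len(populated) == 1
        assert populated[0].observed_rate == pytest.approx(np.mean(y))

    def test_hand_built_two_bins(self):
        y = [0, 0, 1, 0, 1, 1, 1, 0, 1, 1]
        p = [0.1, 0.2, 0.3, 0.4, 0.45, 0.6, 0.7, 0.8, 0.9, 0.95]
        bins = calibration_bins(y, p, n_bins=2)
        assert bins[0].count == 5 and bins[1].count == 5
        assert bins[0].mean_predicted == pytest.approx(np.mean(p[:5]))
        assert bins[0].observed_rate == pytest.approx(np.mean(y[:5]))
        assert bins[1].observed_rate == pytest.approx(np.mean(y[5:]))

    def test_calibrated_synthetic_data(self):
        rng = np.random.default_rng(37)
        p = rng.random(10_000)
        y = (rng.random(10_000) < p).astype(int)
        for b in calibration_bins(y, p, n_bins=10):
            if b.count > 50:
                sd = np.sqrt(b.mean_predicted * (1 - b.mean_predicted) / b.count)
                assert abs(b.mean_predicted - b.observed_rate) <= 3 * sd + 1e-9

    def test_bin_count_validation(self):
        with pytest.raises(ValueError, match="n_bins"):
            calibration_bins([0, 1], [0.1, 0.9], n_bins=1)


class TestAllocation:
    def test_published_counts(self):
        alloc = stratified_allocation({0: 1124, 1: 66}, 0.8)
        assert alloc == {0: 900, 1: 52}


def _threshold_trainer(X_train, y_train, X_val, y_val, params, seed):
    """Deterministic stand-in model: score = x1 shifted by a parameter."""
    shift = params.get("shift", 0.0)
    return lambda df: 1 / (1 + np.exp(-(df["x1"].to_numpy() - shift)))


class TestGridSearch:
    def test_single_grid_point_passthrough(self):
        X, y, _ = make_fixture("separable", seed=3)
        plan = CVPlan(folds=4, grid={"shift": [0.0]}, seed=1)
        best, table = grid_search_cv(X, y, plan, _threshold_trainer)
        assert best == {"shift": 0.0} and len(table) == 1

    def test_sabotaged_setting_loses(self):
        X, y, _ = make_fixture("separable", seed=4)
        plan = CVPlan(folds=4, grid={"shift": [0.0, 50.0]}, seed=1)
        best, table = grid_search_cv(X, y, plan, _threshold_trainer)
        # shift 50 pushes every score to ~0: no positives predicted
        assert best == {"shift": 0.0}
        assert table.loc[table["shift"] == 0.0, "mean_f1"].iloc[0] > \
            table.loc[table["shift"] == 50.0, "mean_f1"].iloc[0]

    def test_single_class_fold_advises_fewer_folds(self):
        X = pd.DataFrame({"x1": np.arange(8.0)})
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        plan = CVPlan(folds=8, grid={"shift": [0.0]})
        with pytest.raises(ValueError, match="fewer folds"):
            grid_search_cv(X, y, plan, _threshold_trainer)

    def test_empty_grid_rejected(self):
        X, y, _ = make_fixture("separable", seed=3)
        with pytest.raises(ValueError, match="grid"):
            grid_search_cv(X, y, CVPlan(grid={}), _threshold_trainer)


class TestRepeatedTestEval:
    def test_full_fraction_equals_single_evaluation(self):
        X, y, _ = make_fixture("separable", seed=5)
        model = lambda df: 1 / (1 + np.exp(-df["x1"].to_numpy()))
        summary, reports = repeated_test_eval(model, X, y, runs=5, fraction=1.0)
        single = evaluate_probabilities(y, model(X))
        for m in ("accuracy", "f1", "auc"):
            assert summary[m]["sd"] == 0.0
            assert summary[m]["mean"] == pytest.approx(getattr(single, m))

    def test_stub_model_hand_average(self):
        # stub returns the label itself: every run is a perfect run
        X = pd.DataFrame({"x1": np.arange(40.0)})
        y = np.array([0, 1] * 20)
        model = lambda df: y[df.index.to_numpy()].astype(float)
        summary, reports = repeated_test_eval(model, X, y, runs=10,
                                              fraction=0.9, seed=3)
        assert len(reports) == 10
        assert summary["f1"]["mean"] == 1.0 and summary["f1"]["sd"] == 0.0
        assert summary["sensitivity"]["n_undefined"] == 0

    def test_rejects_single_class_test_set(self):
        X = pd.DataFrame({"x1": np.arange(6.0)})
        with pytest.raises(ValueError, match="both classes"):
            repeated_test_eval(lambda df: np.zeros(len(df)), X,
                               np.zeros(6, dtype=int))


class TestOverfitGap:
    def test_identical_reports_zero_gap(self):
        rep = evaluate_probabilities([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        gaps = overfit_gap(rep, rep)
        assert all(v == 0 for v in gaps.values() if v is not None)

    def test_published_f1_consistency_gap(self):
        train = {"f1": 0.725}
        test = {"f1": 0.712}
        full = {m: None for m in ("accuracy", "sensitivity", "specificity",
                                  "ppv", "npv", "auc")}
        gaps = overfit_gap({**full, **train}, {**full, **test})
        assert gaps["f1"] == pytest.approx(0.013)
        assert gaps["accuracy"] is None
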