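"""ROC/AUC with DeLong CI and Youden cut-off, logistic nomogram,
optimism-corrected calibration, and decision curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from glympipe.diagnostics import (DiagnosticModel, SeparationError,
                                  build_nomogram, calibration_bootstrap,
                                  calibration_curve, decision_curve,
                                  delong_auc_variance, fit_logistic,
                                  roc_analysis)


def _brute_force_auc(scores, labels):
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = roc_analysis(scores, labels)
        assert res.auc == 1.0
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_hand_counted_aucs(self):
        labels = np.array([0, 0, 1, 1])
        assert roc_analysis(np.array([1.0, 2, 3, 4]), labels).auc == 1.0
        assert roc_analysis(np.array([1.0, 3, 2, 4]), labels).auc == 0.75

    def test_auc_equals_pair_counting_with_ties(self, rng):
        for n in (8, 20, 50):
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            res = roc_analysis(scores, labels, direction="greater")
            assert res.auc == pytest.approx(_brute_force_auc(scores, labels),
                                            abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        a1 = roc_analysis(scores, labels, direction="greater").auc
        a2 = roc_analysis(np.exp(scores), labels, direction="greater").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auto_direction_orients_low_marker(self, rng):
        # lower values indicate disease (like the ALPS index)
        scores = np.concatenate([rng.normal(1.2, 0.16, 41), rng.normal(1.36, 0.14, 43)])
        labels = np.r_[np.ones(41), np.zeros(43)]
        res = roc_analysis(scores, labels)
        assert res.direction == "less"
        assert res.auc > 0.5

    def test_youden_cutoff_maximizes_j(self, rng):
        scores = rng.standard_normal(80)
        labels = (scores + rng.standard_normal(80) > 0).astype(int)
        res = roc_analysis(scores, labels, direction="greater")
        j = res.sensitivity - (1 - res.specificity)
        assert res.sens_at_cutoff + res.spec_at_cutoff - 1 == pytest.approx(j.max())

    def test_delong_ci_contains_auc_and_shrinks(self, rng):
        widths = []
        for n in (50, 500):
            scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
            labels = np.r_[np.ones(n), np.zeros(n)]
            res = roc_analysis(scores, labels, direction="greater")
            assert res.ci95[0] <= res.auc <= res.ci95[1]
            widths.append(res.ci95[1] - res.ci95[0])
        assert widths[1] < widths[0] / 2

    def test_binormal_consistency(self, rng):
        # mean empirical AUC matches Phi(dmu / sqrt(s1^2 + s2^2))
        dmu, s1, s2 = 0.15, 0.13, 0.14
        expected = norm.cdf(dmu / np.hypot(s1, s2))
        aucs = []
        for _ in range(200):
            scores = np.concatenate([rng.normal(0.0, s1, 41), rng.normal(dmu, s2, 43)])
            labels = np.r_[np.zeros(41), np.ones(43)]
            aucs.append(roc_analysis(scores, labels, direction="greater").auc)
        assert np.mean(aucs) == pytest.approx(expected, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5))


class TestDelongVariance:
    def test_auc_equals_mann_whitney_u_ratio(self, rng):
        pos = rng.standard_normal(25) + 0.7
        neg = rng.standard_normal(30)
        auc, var = delong_auc_variance(pos, neg)
        labels = np.r_[np.ones(25), np.zeros(30)]
        assert auc == pytest.approx(
            _brute_force_auc(np.r_[pos, neg], labels), abs=1e-12)
        assert var > 0


class TestFitLogistic:
    def test_null_feature_recovers_prevalence(self, rng):
        x = rng.standard_normal(4000)
        y = rng.random(4000) < 0.3
        model = fit_logistic(x, y)
        assert model.coef[0] == pytest.approx(0.0, abs=0.15)
        assert model.intercept == pytest.approx(logit(y.mean()), abs=0.05)

    def test_parameter_recovery_within_3se(self, rng):
        beta0, beta1 = -1.0, 2.0
        x = rng.standard_normal(5000)
        y = rng.random(5000) < expit(beta0 + beta1 * x)
        model = fit_logistic(x, y)
        assert abs(model.intercept - beta0) < 3 * model.stderr[0]
        assert abs(model.coef[0] - beta1) < 3 * model.stderr[1]

    def test_fitted_probability_auc_matches_raw_feature_auc(self, rng):
        x = rng.standard_normal(200)
        y = (rng.random(200) < expit(1.5 * x)).astype(int)
        model = fit_logistic(x, y)
        a_raw = roc_analysis(x, y, direction="greater").auc
        a_fit = roc_analysis(model.fitted_probabilities, y, direction="greater").auc
        assert a_fit == pytest.approx(a_raw, abs=1e-12)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            fit_logistic(x, y)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x])
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        with pytest.raises(ValueError):
            fit_logistic(X, y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_logistic(rng.standard_normal(20), np.zeros(20))


def _toy_model(coefs, intercept=0.0):
    return DiagnosticModel(
        feature_names=tuple(f"f{i}" for i in range(len(coefs))),
        intercept=intercept,
        coef=np.asarray(coefs, dtype=float),
        fitted_probabilities=np.array([0.5]),
    )


class TestNomogram:
    def test_single_feature_spans_full_scale(self):
        nom = build_nomogram(_toy_model([0.8]), {"f0": (0.0, 5.0)})
        assert nom.feature_points("f0", 0.0) == pytest.approx(0.0)
        assert nom.feature_points("f0", 5.0) == pytest.approx(100.0)

    def test_two_to_one_contribution_ratio(self):
        nom = build_nomogram(_toy_model([2.0, -1.0]),
                             {"f0": (0.0, 1.0), "f1": (0.0, 1.0)})
        assert nom.max_points[0] == pytest.approx(100.0)
        assert nom.max_points[1] == pytest.approx(50.0)
        # negative coefficient anchors at the high end
        assert nom.feature_points("f1", 1.0) == pytest.approx(0.0)
        assert nom.feature_points("f1", 0.0) == pytest.approx(50.0)

    def test_points_reproduce_model_probability(self, rng):
        x = rng.standard_normal((300, 3))
        lp = -0.5 + x @ np.array([1.2, -0.7, 0.4])
        y = rng.random(300) < expit(lp)
        model = fit_logistic(pd.DataFrame(x, columns=["a", "b", "c"]), y)
        ranges = {c: (float(x[:, i].min()), float(x[:, i].max()))
                  for i, c in enumerate(["a", "b", "c"])}
        nom = build_nomogram(model, ranges)
        subjects = x[rng.integers(0, 300, 100)]
        direct = model.predict_proba(subjects)
        via_points = nom.probability_from_points(nom.total_points(subjects))
        np.testing.assert_allclose(via_points, direct, atol=1e-6)

    def test_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            build_nomogram(_toy_model([0.0, 0.0]),
                           {"f0": (0, 1), "f1": (0, 1)})

    def test_missing_range_rejected(self):
        with pytest.raises(ValueError):
            build_nomogram(_toy_model([1.0]), {})


class TestCalibration:
    def test_well_specified_model_close_to_identity(self, rng):
        x = rng.standard_normal(2000)
        y = rng.random(2000) < expit(0.3 + 1.2 * x)
        model = fit_logistic(x, y)
        cal = calibration_bootstrap(model, x, y, n_boot=50, seed=0)
        valid = cal.dropna(subset=["observed_corrected"])
        assert len(valid) >= 5
        np.testing.assert_allclose(valid["observed_corrected"],
                                   valid["mean_predicted"], atol=0.05)

    def test_squared_probabilities_underpredict_at_low_p(self, rng):
        true_p = rng.uniform(0.05, 0.95, 5000)
        y = rng.random(5000) < true_p
        edges = np.linspace(0, 1, 11)
        curve = calibration_curve(true_p**2, y, edges)
        low = curve.dropna().iloc[:3]
        assert (low["observed"] > low["mean_predicted"]).all()

    def test_zero_bootstrap_rejected(self, rng):
        x = rng.standard_normal(100)
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        model = fit_logistic(x, y)
        with pytest.raises(ValueError):
            calibration_bootstrap(model, x, y, n_boot=0)


class TestDecisionCurve:
    def test_low_threshold_limit_approaches_prevalence(self, rng):
        p = rng.uniform(0.2, 0.9, 500)
        y = rng.random(500) < p
        curve = decision_curve(p, y, [0.001])
        prevalence = y.mean()
        assert curve["net_benefit_model"].iloc[0] == pytest.approx(prevalence, abs=0.01)
        assert curve["net_benefit_all"].iloc[0] == pytest.approx(prevalence, abs=0.01)
        assert curve["net_benefit_none"].iloc[0] == 0.0

    def test_perfect_probabilities_give_constant_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(bool)
        p = y.astype(float)
        curve = decision_curve(p, y, np.arange(0.05, 1.0, 0.05))
        np.testing.assert_allclose(curve["net_benefit_model"], 0.3, atol=1e-12)

    def test_uninformative_model_dominated_by_references(self, rng):
        y = rng.random(2000) < 0.4
        p = rng.uniform(0, 1, 2000)  # independent of labels
        curve = decision_curve(p, y, np.arange(0.05, 0.95, 0.05))
        slack = 0.03
        best_ref = np.maximum(curve["net_benefit_all"], 0.0)
        assert (curve["net_benefit_model"] <= best_ref + slack).all()

    def test_bad_grids_rejected(self, rng):
        p = rng.uniform(0, 1, 10)
        y = rng.integers(0, 2, 10)
        with pytest.raises(ValueError):
            decision_curve(p, y, [])
        with pytest.raises(ValueError):
            decision_curve(p, y, [0.0, 0.5])
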