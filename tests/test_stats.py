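"""Group comparisons with normality gating, FDR-corrected correlations,
partial correlation, and ICC reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from glympipe.stats import (compare_groups, correlation_matrix,
                            icc_reproducibility, partial_correlation)


class TestCompareGroups:
    def test_gaussian_samples_use_student_t(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.2, 1, 100)
        res = compare_groups(a, b, variable="x")
        assert res.test_used == "student_t"
        assert "±" in res.summary_a

    def test_lognormal_sample_switches_to_mann_whitney(self, rng):
        a = np.exp(rng.normal(0, 0.8, 43))  # heavy skew fails Shapiro at n=43
        b = rng.normal(1, 0.3, 41)
        res = compare_groups(a, b)
        assert res.test_used == "mann_whitney"
        assert "(" in res.summary_a  # median (IQR) formatting

    def test_pooled_t_matches_closed_form_on_three_points(self):
        # hand-checkable samples: a = (1, 2, 3), b = (4, 5, 6)
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        res = compare_groups(a, b)
        # pooled sd = 1, se = sqrt(1/3 + 1/3), t = -3 / se
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        assert res.test_used == "student_t"
        assert res.statistic == pytest.approx(t_expected)
        assert res.p == pytest.approx(2 * sst.t.sf(abs(t_expected), 4))

    def test_mann_whitney_matches_brute_force_pair_count(self, rng):
        # exponential data reliably fails Shapiro at these sizes
        for _ in range(5):
            a = rng.exponential(1.0, 8) ** 3
            b = rng.exponential(1.0, 7) ** 3
            res = compare_groups(a, b)
            if res.test_used != "mann_whitney":
                continue
            u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert res.statistic == pytest.approx(u_brute)

    def test_table2_parameterized_coupling_groups_differ(self, marker_table):
        als = marker_table.query("group == 'ALS'")["coupling_index"]
        hc = marker_table.query("group == 'HC'")["coupling_index"]
        res = compare_groups(als, hc)
        assert res.p < 0.001

    def test_type_i_error_near_alpha_under_null(self, rng):
        reps, rejections = 200, 0
        for _ in range(reps):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            rejections += compare_groups(a, b).p <= 0.05
        assert abs(rejections / reps - 0.05) < 0.045

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(30)})
        df["x2"] = df["x"]
        entry = correlation_matrix(df, [("x", "x2")])[0]
        assert entry.r == pytest.approx(1.0)

    def test_bh_matches_stepup_oracle(self, rng):
        # independent oracle: Benjamini-Hochberg computed by hand in-test
        df = pd.DataFrame(rng.standard_normal((25, 6)),
                          columns=list("abcdef"))
        df["g"] = df["a"] * 0.8 + rng.standard_normal(25) * 0.4
        pairs = [("a", "g"), ("b", "c"), ("d", "e"), ("a", "f"), ("c", "g")]
        entries = correlation_matrix(df, pairs)
        p = np.array([e.p for e in entries])
        m = len(p)
        order = np.argsort(p)
        q_oracle = np.empty(m)
        running_min = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            running_min = min(running_min, p[idx] * m / rank)
            q_oracle[idx] = running_min
        np.testing.assert_allclose([e.q for e in entries], q_oracle, rtol=1e-12)

    def test_q_at_least_p_and_monotone_in_rank(self, rng):
        df = pd.DataFrame(rng.standard_normal((40, 8)),
                          columns=list("abcdefgh"))
        pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h"), ("a", "h")]
        entries = correlation_matrix(df, pairs)
        by_p = sorted(entries, key=lambda e: e.p)
        assert all(e.q >= e.p for e in entries)
        assert all(x.q <= y.q for x, y in zip(by_p, by_p[1:]))

    def test_equal_p_values_share_q(self, rng):
        # q = p * m / m = p when every pair has the same p; check via a
        # family of identical pairs
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        df = pd.DataFrame({"x": x, "y": y, "x2": x, "y2": y})
        entries = correlation_matrix(df, [("x", "y"), ("x2", "y2")])
        assert entries[0].q == pytest.approx(entries[0].p)
        assert entries[1].q == pytest.approx(entries[1].p)

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            correlation_matrix(df, [("x", "y")])

    def test_family_recovery_of_imposed_correlation(self, marker_table):
        als = marker_table.query("group == 'ALS'")
        entry = correlation_matrix(als, [("alps_index", "cpv_fraction_pct")])[0]
        # single cohort at n=41: wide sampling band around -0.537
        assert -0.85 < entry.r < -0.2
        assert entry.n == 41


class TestPartialCorrelation:
    def test_independent_covariate_leaves_r_unchanged(self, rng):
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        c = rng.standard_normal(200)
        plain = np.corrcoef(x, y)[0, 1]
        entry = partial_correlation(x, y, c)
        assert entry.r == pytest.approx(plain, abs=0.05)

    def test_y_equal_to_covariate_gives_zero(self, rng):
        x = rng.standard_normal(100)
        c = rng.standard_normal(100)
        entry = partial_correlation(x, c, c)
        assert entry.r == pytest.approx(0.0, abs=1e-8)

    def test_matches_closed_form_for_trivariate_gaussian(self):
        # partial r = (rxy - rxz*ryz) / sqrt((1-rxz^2)(1-ryz^2)) applied to
        # the *sample* correlations, exactly
        rng = np.random.default_rng(77)
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.6], [0.3, 0.6, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=500)
        x, y, c = data.T
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, c)[0, 1]
        ryz = np.corrcoef(y, c)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        entry = partial_correlation(x, y, c)
        assert entry.r == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(80)
        c = 0.5 * x + rng.standard_normal(80)
        y = -0.4 * x + 0.3 * c + rng.standard_normal(80)
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        entry = partial_correlation(x, y, c)
        assert entry.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert entry.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_constant_covariate_falls_back_with_warning(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        with pytest.warns(UserWarning):
            entry = partial_correlation(x, y, np.ones(50))
        assert entry.r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestIcc:
    def test_identical_measurements_give_unit_icc(self, rng):
        x = rng.standard_normal(30)
        res = icc_reproducibility(np.column_stack([x, x]))
        assert res["icc_consistency"] == pytest.approx(1.0)
        assert res["icc_agreement"] == pytest.approx(1.0)

    def test_nine_to_one_variance_ratio_gives_point_nine(self, rng):
        truth = rng.normal(0, 3.0, 3000)
        ratings = np.column_stack([truth + rng.standard_normal(3000),
                                   truth + rng.standard_normal(3000)])
        res = icc_reproducibility(ratings)
        assert res["icc_consistency"] == pytest.approx(0.9, abs=0.02)
        assert res["icc_agreement"] == pytest.approx(0.9, abs=0.02)

    def test_independent_measurements_give_near_zero(self, rng):
        ratings = rng.standard_normal((2000, 2))
        res = icc_reproducibility(ratings)
        assert abs(res["icc_consistency"]) < 0.08

    def test_agrees_with_pingouin_forms(self, rng):
        pingouin = pytest.importorskip("pingouin")
        truth = rng.normal(0, 2.0, 40)
        ratings = np.column_stack([truth + rng.standard_normal(40),
                                   truth + 0.5 + rng.standard_normal(40)])
        res = icc_reproducibility(ratings)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(40), 2),
            "rater": np.tile(["m1", "m2"], 40),
            "score": ratings.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        assert res["icc_consistency"] == pytest.approx(
            float(ref.loc["ICC(C,1)", "ICC"]), abs=1e-9)
        assert res["icc_agreement"] == pytest.approx(
            float(ref.loc["ICC(A,1)", "ICC"]), abs=1e-9)

    def test_systematic_shift_penalized_only_by_agreement_form(self, rng):
        truth = rng.normal(0, 1.0, 500)
        shifted = np.column_stack([truth, truth + 2.0])
        res = icc_reproducibility(shifted)
        assert res["icc_consistency"] > 0.99
        assert res["icc_agreement"] < 0.5

    def test_missing_measurement_rejected(self):
        ratings = np.ones((10, 2))
        ratings[3, 1] = np.nan
        with pytest.raises(ValueError):
            icc_reproducibility(ratings)
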