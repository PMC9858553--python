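"""Odds ratios, logistic regression, group tests, correlation panel."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from spise.roc import sex_stratified_cutoffs
from spise.stats import (TwoByTwo, compare_groups, correlation_panel,
                         fit_logistic, odds_ratio,
                         stratified_component_table)


class TestOddsRatio:
    def test_published_waist_table(self):
        est = odds_ratio(TwoByTwo(52, 51, 10, 339))
        assert round(est.or_value, 2) == 34.56
        assert round(est.ci_low, 1) == 16.5
        assert round(est.ci_high, 1) == 72.3

    def test_balanced_table(self):
        assert odds_ratio(TwoByTwo(10, 10, 10, 10)).or_value == pytest.approx(1.0)

    def test_zero_cell_undefined(self):
        est = odds_ratio(TwoByTwo(26, 102, 0, 282))
        assert not est.defined and np.isnan(est.or_value)

    def test_haldane_correction_defines_zero_cell(self):
        est = odds_ratio(TwoByTwo(26, 102, 0, 282), haldane=True)
        assert est.defined and est.or_value > 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)

    def test_exposure_flip_inverts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = TwoByTwo(*rng.integers(1, 50, size=4))
            prod = odds_ratio(t).or_value * odds_ratio(t.flipped_exposure()).or_value
            assert prod == pytest.approx(1.0, rel=1e-12)

    def test_ci_contains_point_and_shrinks(self):
        t = TwoByTwo(12, 7, 9, 30)
        est = odds_ratio(t)
        assert est.ci_low <= est.or_value <= est.ci_high
        est10 = odds_ratio(TwoByTwo(120, 70, 90, 300))
        assert (est10.ci_high - est10.ci_low) < (est.ci_high - est.ci_low)
        assert est10.or_value == pytest.approx(est.or_value)


class TestLogistic:
    @staticmethod
    def expand(table):
        a, b, c, d = table.a, table.b, table.c, table.d
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        return y, np.column_stack([np.ones(y.size), x])

    def test_matches_closed_form_on_published_table(self):
        t = TwoByTwo(52, 51, 10, 339)
        y, X = self.expand(t)
        fit = fit_logistic(y, X)
        assert fit.converged
        assert np.exp(fit.params[1]) == pytest.approx(odds_ratio(t).or_value,
                                                      rel=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_separation_flagged_not_silent(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        X = np.column_stack([np.ones(10), np.r_[np.ones(5) * 2, np.zeros(5)]])
        with pytest.warns(UserWarning):
            fit = fit_logistic(y, X)
        assert not fit.converged and fit.message

    def test_against_statsmodels(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(300), rng.normal(size=300),
                             rng.integers(0, 2, 300)])
        eta = 0.3 - 0.8 * X[:, 1] + 0.5 * X[:, 2]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.params, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, rtol=1e-4)

    def test_age_adjustment_collapsible_under_independence(self):
        """With age independent of exposure, the age-adjusted OR stays close
        to the unadjusted one (collapsibility holds approximately here)."""
        rng = np.random.default_rng(2)
        n = 4000
        exposed = rng.random(n) < 0.4
        age = rng.uniform(10, 17, n)
        eta = -2.0 + 1.2 * exposed
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        unadj = fit_logistic(y, np.column_stack([np.ones(n), exposed]))
        adj = fit_logistic(y, np.column_stack([np.ones(n), exposed, age]))
        assert np.exp(adj.params[1]) == pytest.approx(np.exp(unadj.params[1]),
                                                      rel=0.05)


class TestCompareGroups:
    def test_identical_groups_null_t(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]}, "gaussian")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_t_hand_value(self):
        res = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]}, "gaussian")
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)

    def test_chi_square_hand_value(self):
        res = compare_groups({"g1": ["x"] * 10 + ["y"] * 20,
                              "g2": ["x"] * 20 + ["y"] * 10}, "categorical")
        assert res.statistic == pytest.approx(20 / 3, rel=1e-9)

    def test_shift_invariance_of_p_values(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=30), rng.normal(1, 1, size=30)
        for kind in ("gaussian", "nongaussian"):
            p0 = compare_groups({"a": a, "b": b}, kind).p_value
            p1 = compare_groups({"a": a + 7, "b": b + 7}, kind).p_value
            assert p0 == pytest.approx(p1, rel=1e-9)

    def test_nongaussian_reports_quartiles(self):
        res = compare_groups({"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5]},
                             "nongaussian")
        assert res.summary["a"]["median"] == 2.5
        assert res.summary["a"]["q1"] == 1.75

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]}, "gaussian")


class TestCorrelationPanel:
    def test_self_correlation(self):
        x = np.array([1.0, 2, 3, 4])
        res = correlation_panel(x, {"x": x})[0]
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = correlation_panel(np.array([1.0, 2, 3]),
                                {"y": np.array([6.0, 5, 4])})[0]
        assert res.r == pytest.approx(-1.0)

    def test_affine_invariance_before_log(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r0 = correlation_panel(x, {"y": y})[0].r
        r1 = correlation_panel(x, {"y": 3.5 * y + 11})[0].r
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_log_transform_applied(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        y = np.exp(x + rng.normal(scale=0.1, size=100))
        r_log = correlation_panel(x, {"y": y}, nongaussian_set={"y"})[0]
        r_raw = correlation_panel(x, {"y": y})[0]
        assert r_log.transformed and not r_raw.transformed
        assert r_log.r > r_raw.r

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_panel(np.array([1.0, 2, 3]), {"y": np.ones(3)})


class TestStratifiedTable:
    def test_counts_and_or_match_closed_form(self, scored):
        cohort, panels, profiles = scored
        cuts = sex_stratified_cutoffs(cohort, panels, profiles)
        table = stratified_component_table(cohort, panels, profiles,
                                           {s: r["cutoff"] for s, r in cuts.items()})
        row = table[(table.sex == "male") & (table.outcome == "mets")].iloc[0]
        t = TwoByTwo(row.cases_low, row.n_low - row.cases_low,
                     row.cases_high, row.n_high - row.cases_high)
        est = odds_ratio(t)
        assert row["or"] == pytest.approx(est.or_value, rel=1e-12)
        assert row["ci_low"] == pytest.approx(est.ci_low, rel=1e-12)
        # adjusted OR exists and is positive for the headline row
        assert row["or_adj"] > 0

    def test_null_association_gives_or_near_one(self):
        """Random exposure labels produce ORs scattered around 1."""
        rng = np.random.default_rng(6)
        ors = []
        for _ in range(40):
            case = rng.random(400) < 0.3
            exposed = rng.random(400) < 0.5
            t = TwoByTwo(int((case & exposed).sum()), int((~case & exposed).sum()),
                         int((case & ~exposed).sum()), int((~case & ~exposed).sum()))
            est = odds_ratio(t)
            if est.defined:
                ors.append(np.log(est.or_value))
        assert abs(np.mean(ors)) < 0.15
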