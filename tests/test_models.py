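"""Conditional/unconditional logistic fits, LRT, trend test, descriptives.

The conditional fitter is cross-checked against closed forms (the matched-
pair odds ratio is the ratio of discordant counts), a dense grid-search
maximizer, and statsmodels' ConditionalLogit as an independent oracle.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medgxe import models
from medgxe.models import (
    clogit_fit,
    cohort_descriptives,
    interaction_design,
    logit_fit,
    lrt_interaction,
    or_report,
    pair_difference_design,
    quartile_median_covariate,
)
from medgxe.simulate import simulate_matched_pairs


class TestConditionalLogit:
    def test_null_loglik_closed_form(self):
        d = pd.DataFrame({"x": [1.0, -1.0, 0.0, 1.0]})
        fit = clogit_fit(d)
        # at beta = 0 the conditional log-likelihood is n*ln(1/2)
        p_half = 4 * np.log(0.5)
        assert fit.loglik >= p_half  # MLE can only improve on the null

    def test_discordant_pair_closed_form(self):
        # 30 case-exposed-only vs 10 control-exposed-only pairs: the matched
        # -pair odds ratio is 30/10, so beta = ln 3
        d = pd.DataFrame({"x": [1.0] * 30 + [-1.0] * 10})
        fit = clogit_fit(d)
        assert fit.converged
        assert fit.beta["x"] == pytest.approx(np.log(3), abs=1e-6)
        # grid-search oracle over the 1-d likelihood surface
        grid = np.linspace(-3, 3, 120001)
        ll = np.array(
            [30 * -np.log1p(np.exp(-b)) + 10 * -np.log1p(np.exp(b)) for b in grid]
        )
        assert grid[ll.argmax()] == pytest.approx(fit.beta["x"], abs=1e-4)

    def test_three_pair_toy_matches_grid_search(self):
        d = pd.DataFrame({"x": [0.7, -0.3, 1.4]})
        fit = clogit_fit(d)
        grid = np.linspace(-6, 6, 240001)
        x = d["x"].to_numpy()[:, None]
        ll = -np.log1p(np.exp(-(x * grid))).sum(axis=0)
        assert ll.max() == pytest.approx(fit.loglik, abs=1e-4)
        assert grid[ll.argmax()] == pytest.approx(fit.beta["x"], abs=1e-3)

    def test_matches_statsmodels_conditional_logit(self, rng):
        # independent oracle on subject-level matched data
        diffs = simulate_matched_pairs(400, 0.4, -0.2, 0.1, rng)
        fit = clogit_fit(diffs)
        from statsmodels.discrete.conditional_models import ConditionalLogit

        n = len(diffs)
        X = np.vstack([diffs.to_numpy(), np.zeros((n, 3))])  # case rows, control rows
        y = np.r_[np.ones(n), np.zeros(n)]
        groups = np.r_[np.arange(n), np.arange(n)]
        sm_fit = ConditionalLogit(y, X, groups=groups).fit(disp=0)
        np.testing.assert_allclose(fit.beta.to_numpy(), sm_fit.params, atol=1e-4)
        np.testing.assert_allclose(fit.se.to_numpy(), sm_fit.bse, rtol=1e-3)

    def test_concordant_pairs_do_not_move_estimate(self, rng):
        diffs = simulate_matched_pairs(300, 0.4, -0.2, 0.0, rng)
        fit = clogit_fit(diffs)
        padded = pd.concat(
            [diffs, pd.DataFrame(np.zeros((50, 3)), columns=diffs.columns)],
            ignore_index=True,
        )
        fit2 = clogit_fit(padded)
        np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-8)
        # loglik shifts by exactly 50*ln(1/2), so LRTs are unchanged
        assert fit2.loglik == pytest.approx(fit.loglik + 50 * np.log(0.5))

    def test_separation_flagged_not_raised(self):
        d = pd.DataFrame({"x": [1.0] * 12})
        fit = clogit_fit(d)
        assert not fit.converged
        assert any("separation" in msg for msg in fit.diagnostics)

    def test_no_discordant_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="discordant"):
            clogit_fit(pd.DataFrame({"x": [0.0, 0.0]}))


class TestUnconditionalLogit:
    def test_intercept_only_at_half_prevalence(self):
        y = np.r_[np.ones(25), np.zeros(25)]
        fit = logit_fit(pd.DataFrame(index=range(50)), y)
        assert fit.beta["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_closed_form(self):
        # table (a,b; c,d) = (20,10; 10,20): slope = ln(ad/bc) = ln 4
        x = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        fit = logit_fit(pd.DataFrame({"x": x}), y)
        assert fit.beta["x"] == pytest.approx(np.log(4), abs=1e-8)

    def test_matches_statsmodels_logit(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.integers(0, 2, n).astype(float)})
        eta = -0.5 + 0.8 * X["a"] - 0.3 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logit_fit(X, y)
        import statsmodels.api as sm

        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.beta.to_numpy(), sm_fit.params.to_numpy(), atol=1e-6)
        assert fit.loglik == pytest.approx(sm_fit.llf)

    def test_parameter_recovery_large_n(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        eta = -1.0 + 0.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logit_fit(pd.DataFrame({"x": x}), y)
        for term, truth in [("intercept", -1.0), ("x", 0.5)]:
            assert abs(fit.beta[term] - truth) < 3 * fit.se[term]

    def test_rank_deficiency_rejected(self, rng):
        X = pd.DataFrame({"a": np.ones(20), "b": np.ones(20)})
        with pytest.raises(ValueError, match="rank"):
            logit_fit(X, np.r_[np.ones(10), np.zeros(10)])

    def test_clogit_equals_interceptfree_logit_on_differences(self, rng):
        # internal cross-check between the two independent code paths
        diffs = simulate_matched_pairs(500, 0.3, -0.15, -0.1, rng)
        a = clogit_fit(diffs)
        b = logit_fit(diffs, np.ones(len(diffs)), add_intercept=False)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)


class TestLRT:
    def test_equal_likelihood_models_give_zero(self, rng):
        diffs = simulate_matched_pairs(200, 0.3, -0.15, 0.0, rng)
        fit = clogit_fit(diffs)
        # a model identical in fit to itself: chi2 = 0, p = 1 (df forced to 1)
        t = lrt_interaction(fit, fit, df=1)
        assert t.lr_chi2 == 0.0 and t.p_value == pytest.approx(1.0)
        reduced = clogit_fit(diffs[["carrier", "mds_q"]])
        assert lrt_interaction(fit, reduced).lr_chi2 >= 0

    def test_negative_delta_is_an_error(self):
        good = models.FitResult(
            pd.Series([0.0], index=["x"]), pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
            loglik=-10.0, n_obs=5, converged=True,
        )
        bad = models.FitResult(
            pd.Series([0.0, 0.0], index=["x", "z"]),
            pd.DataFrame(np.eye(2), index=["x", "z"], columns=["x", "z"]),
            loglik=-12.0, n_obs=5, converged=True,
        )
        with pytest.raises(ValueError, match="log-likelihood"):
            lrt_interaction(bad, good)

    def test_invariant_to_affine_recoding(self, rng):
        diffs = simulate_matched_pairs(400, 0.3, -0.15, -0.2, rng)
        full = clogit_fit(diffs)
        red = clogit_fit(diffs[["carrier", "mds_q"]])
        t1 = lrt_interaction(full, red)
        recoded = diffs.copy()
        recoded["mds_q"] = 10 * recoded["mds_q"]  # affine recode of covariate
        recoded["gxe"] = 10 * recoded["gxe"]
        t2 = lrt_interaction(
            clogit_fit(recoded), clogit_fit(recoded[["carrier", "mds_q"]])
        )
        assert t1.lr_chi2 == pytest.approx(t2.lr_chi2, abs=1e-6)

    def test_power_exceeds_size_and_grows_with_n(self, rng):
        def rejection_rate(n_pairs, beta_gxe, reps=60):
            rej = 0
            for _ in range(reps):
                d = simulate_matched_pairs(n_pairs, 0.3, -0.15, beta_gxe, rng)
                t = lrt_interaction(clogit_fit(d), clogit_fit(d[["carrier", "mds_q"]]))
                rej += t.p_value < 0.05
            return rej / reps

        power_small = rejection_rate(300, 0.5)
        power_large = rejection_rate(1500, 0.5)
        assert power_large > 0.6
        assert power_large >= power_small


class TestTrendAndReports:
    def test_trend_slope_null_when_rates_equal(self, rng):
        # no outcome gradient across quartiles -> slope compatible with 0
        n = 2000
        q = rng.integers(1, 5, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        mds = q + rng.random(n)  # any score consistent with the quartile
        trend = quartile_median_covariate(pd.Series(q), pd.Series(mds))
        fit = logit_fit(pd.DataFrame({"trend": trend}), y)
        assert abs(fit.beta["trend"]) < 3 * fit.se["trend"]
        assert models.trend_test(fit) > 0.001

    def test_trend_p_uniform_under_null(self, rng):
        pvals = []
        for _ in range(200):
            q = rng.integers(1, 5, 300).astype(float)
            y = (rng.random(300) < 0.5).astype(float)
            fit = logit_fit(pd.DataFrame({"trend": q}), y)
            pvals.append(models.trend_test(fit))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_quartile_median_covariate_values(self):
        q = pd.Series([1, 1, 2, 2, 2, 3, 4, 4], dtype=float)
        mds = pd.Series([0, 2, 3, 4, 5, 5, 7, 8], dtype=float)
        trend = quartile_median_covariate(q, mds)
        assert trend.tolist() == [1.0, 1.0, 4.0, 4.0, 4.0, 5.0, 7.5, 7.5]

    def test_or_report_values(self):
        fit = models.FitResult(
            pd.Series([0.0, np.log(2)], index=["a", "b"]),
            pd.DataFrame(np.diag([0.01, 0.04]), index=["a", "b"], columns=["a", "b"]),
            loglik=-1.0, n_obs=10, converged=True,
        )
        rep = or_report(fit).set_index("term")
        assert rep.loc["a", "or"] == pytest.approx(1.0)
        assert rep.loc["a", "ci_low"] == pytest.approx(np.exp(-1.96 * 0.1), abs=1e-4)
        assert rep.loc["a", "ci_high"] == pytest.approx(np.exp(1.96 * 0.1), abs=1e-4)
        assert rep.loc["b", "or"] == pytest.approx(2.0)
        assert ((rep["ci_low"] <= rep["or"]) & (rep["or"] <= rep["ci_high"])).all()


class TestDescriptives:
    def test_identical_groups_give_p_one(self, rng):
        df = pd.DataFrame(
            {"age": rng.normal(35, 10, 100), "smoking": rng.choice(["never", "current"], 100)}
        )
        out = cohort_descriptives(df, df.copy(), continuous=["age"], categorical=["smoking"])
        assert np.allclose(out["p"].to_numpy(), 1.0)

    def test_planted_mean_shift_detected(self, rng):
        a = pd.DataFrame({"age": rng.normal(35, 10, 200)})
        # shift the same draws by ~4 standard errors of the difference
        delta = 4 * a["age"].std() * np.sqrt(2 / 200)
        b = pd.DataFrame({"age": a["age"] + delta})
        out = cohort_descriptives(a, b, continuous=["age"])
        assert out["p"].iloc[0] < 0.05

    def test_chi_square_matches_textbook_formula(self):
        # printed 2x2: exposure 30/70 in cases vs 50/50 in controls
        cases = pd.DataFrame({"edu": ["hi"] * 30 + ["lo"] * 70})
        controls = pd.DataFrame({"edu": ["hi"] * 50 + ["lo"] * 50})
        out = cohort_descriptives(cases, controls, categorical=["edu"])
        a, b, c, d = 30, 70, 50, 50
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert out["p"].iloc[0] == pytest.approx(float(stats.chi2.sf(chi2, 1)))


class TestDesignHelpers:
    def test_pair_difference_design(self):
        cov = pd.DataFrame(
            {"x": [1.0, 0.0, 2.0, 5.0]}, index=["c1", "k1", "c2", "k2"]
        )
        pairs = pd.DataFrame({"case_id": ["c1", "c2"], "control_id": ["k1", "k2"]})
        d = pair_difference_design(pairs, cov, ["x"])
        assert d["x"].tolist() == [1.0, -3.0]

    def test_interaction_design_ordinal_and_categorical(self, rng):
        df = pd.DataFrame(
            {
                "carrier": rng.integers(0, 2, 40).astype(float),
                "q": rng.integers(1, 5, 40).astype(float),
                "edu": rng.integers(0, 2, 40).astype(float),
            }
        )
        full, red = interaction_design(df, "carrier", "q", adjust=["edu"])
        assert list(full.columns) == ["carrier", "mds_q", "gxe", "edu"]
        assert (full["gxe"] == full["carrier"] * full["mds_q"]).all()
        full3, red3 = interaction_design(df, "carrier", "q", ordinal=False)
        assert len(full3.columns) - len(red3.columns) == 3
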