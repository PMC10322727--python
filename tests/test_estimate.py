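"""Logistic fitting, proper imputation, and Rubin's-rules pooling."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from ccbias import (
    ScenarioSpec,
    chained_imputation,
    complete_case_estimate,
    draw_cohort,
    fit_logistic,
    impute_once,
    mi_estimate,
    pool,
    rng_stream,
    simulate_replicate,
)


def _design(*cols):
    return np.column_stack([np.ones(len(cols[0])), *cols])


class TestFitLogistic:
    def test_balanced_symmetry_gives_null(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        x = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_logistic(y, _design(x))
        assert fit.converged
        assert fit.estimate == pytest.approx(0.0, abs=1e-8)

    def test_grouped_2x2_equals_log_cross_product(self):
        # proxy-accuracy counts: (tn, fp, fn, tp) = (3012, 72, 199, 71)
        d = np.repeat([0.0, 0.0, 1.0, 1.0], [3012, 72, 199, 71])
        a = np.repeat([0.0, 1.0, 0.0, 1.0], [3012, 72, 199, 71])
        fit = fit_logistic(d, _design(a))
        expected = math.log((3012 * 71) / (72 * 199))
        assert fit.estimate == pytest.approx(expected, abs=1e-8)
        assert fit.estimate == pytest.approx(2.70, abs=0.01)

    @pytest.mark.parametrize("binary_design", [True, False])
    def test_matches_statsmodels_oracle(self, binary_design):
        """MLE and Wald SEs agree with the GLM IRLS reference implementation."""
        rng = np.random.default_rng(42)
        n = 4000
        x = (rng.random(n) < 0.3).astype(float)
        z = (rng.random(n) < 0.2).astype(float) if binary_design else rng.standard_normal(n)
        d = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 0.4 * x + 0.7 * z)))).astype(float)
        X = _design(x, z)
        fit = fit_logistic(d, X)
        ref = sm.GLM(d, X, family=sm.families.Binomial()).fit()
        assert fit.params == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse[1], abs=1e-6)
        assert np.sqrt(np.diag(fit.cov)) == pytest.approx(ref.bse, abs=1e-6)

    def test_separation_flagged_not_silent(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        x = y.copy()  # perfect prediction
        fit = fit_logistic(y, _design(x))
        assert not fit.converged
        assert fit.message

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros(10), _design(np.arange(10.0)))

    def test_rank_deficient_design_rejected(self):
        y = np.array([0.0, 1.0] * 5)
        x = np.ones(10)
        with pytest.raises(ValueError):
            fit_logistic(y, _design(x))


class TestCompleteCase:
    def test_no_missingness_equals_full_fit(self):
        spec = ScenarioSpec(n=5000, seed=1)
        cohort = draw_cohort(spec, rng_stream(spec.seed, 0, 0))
        cc = complete_case_estimate(cohort)
        full = fit_logistic(cohort["d"].to_numpy(),
                            _design(cohort["x"].to_numpy(float)))
        assert cc.estimate == full.estimate
        assert cc.n_used == len(cohort)

    def test_n_used_counts_observed_records(self):
        spec = ScenarioSpec(n=10_000, factor1=0.4, seed=2)
        cohort = simulate_replicate(spec, 0)
        cc = complete_case_estimate(cohort)
        assert cc.n_used == int((cohort["r"] == 1).sum())


class TestImputeOnce:
    def test_no_missing_outcome_returned_unchanged(self):
        spec = ScenarioSpec(n=3000, seed=4)
        cohort = draw_cohort(spec, rng_stream(spec.seed, 0, 0))
        out = impute_once(cohort, rng_stream(spec.seed, 0, 3))
        assert (out == cohort["d"].to_numpy()).all()

    def test_deterministic_given_stream(self):
        spec = ScenarioSpec(n=10_000, factor1=0.4, seed=4)
        cohort = simulate_replicate(spec, 0)
        out1 = impute_once(cohort, rng_stream(7, 0, 3))
        out2 = impute_once(cohort, rng_stream(7, 0, 3))
        assert (out1 == out2).all()
        assert np.isnan(cohort["d"]).any() and not np.isnan(out1).any()

    def test_partially_observed_proxy_refused(self):
        spec = ScenarioSpec(n=5000, factor1=0.4, factor4=0.25, factor3=True, seed=4)
        cohort = simulate_replicate(spec, 0)
        with pytest.raises(ValueError):
            impute_once(cohort, rng_stream(7, 0, 3))

    def test_mar_given_proxy_recovers_full_data_fit(self):
        """Selection on the observed proxy is exactly MAR, and because the
        proxy is conditionally independent of exposure given the outcome the
        main-effects imputation model is exactly specified — the imputed fit
        must centre on the full-data fit."""
        diffs = []
        for rep in range(40):
            spec = ScenarioSpec(n=10_000, seed=31)
            cohort = draw_cohort(spec, rng_stream(spec.seed, rep, 0))
            full = fit_logistic(cohort["d"].to_numpy(),
                                _design(cohort["x"].to_numpy(float))).estimate
            # mask outcomes with probability depending on the observed proxy
            rng = rng_stream(spec.seed, rep, 1)
            p_obs = np.where(cohort["a"] == 1, 0.4, 0.7)
            r = (rng.random(len(cohort)) < p_obs).astype(int)
            masked = cohort.copy()
            masked["r"] = r
            masked.loc[r == 0, ["y", "d"]] = np.nan
            d_imp = impute_once(masked, rng_stream(spec.seed, rep, 3))
            imp = fit_logistic(d_imp, _design(masked["x"].to_numpy(float))).estimate
            diffs.append(imp - full)
        diffs = np.asarray(diffs)
        mc3 = 3 * diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert diffs.mean() == pytest.approx(0.0, abs=max(mc3, 0.01))

    def test_perfect_proxy_separation_is_flagged(self):
        """a == d makes the imputation model perfectly separated; this must
        surface as an error, never as silent divergent coefficients."""
        spec = ScenarioSpec(n=5000, factor1=0.4, factor2=1.0, specificity=1.0,
                            seed=31)
        cohort = simulate_replicate(spec, 0)
        with pytest.raises(RuntimeError):
            impute_once(cohort, rng_stream(spec.seed, 0, 3))


class TestChainedImputation:
    def test_fully_observed_proxy_reduces_to_single_imputation(self):
        spec = ScenarioSpec(n=10_000, factor1=0.4, seed=6)
        cohort = simulate_replicate(spec, 0)
        d1, a1 = chained_imputation(cohort, rng_stream(3, 0, 3))
        d2 = impute_once(cohort, rng_stream(3, 0, 3))
        assert (d1 == d2).all()
        assert (a1 == cohort["a"].to_numpy()).all()

    def test_fully_observed_outcome_imputes_proxy_only(self):
        spec = ScenarioSpec(n=5000, factor4=0.25, factor3=True, seed=6)
        cohort = draw_cohort(spec, rng_stream(spec.seed, 0, 0))
        cohort = cohort.copy()
        rng = rng_stream(spec.seed, 0, 2)
        cohort.loc[rng.random(len(cohort)) < 0.25, "a"] = np.nan
        d, a = chained_imputation(cohort, rng_stream(3, 0, 3))
        assert (d == cohort["d"].to_numpy()).all()
        assert not np.isnan(a).any()

    def test_completes_both_variables_deterministically(self):
        spec = ScenarioSpec(n=10_000, factor1=0.4, factor3=True, factor4=0.25, seed=6)
        cohort = simulate_replicate(spec, 0)
        d1, a1 = chained_imputation(cohort, rng_stream(5, 0, 3), burn_in=5)
        d2, a2 = chained_imputation(cohort, rng_stream(5, 0, 3), burn_in=5)
        assert (d1 == d2).all() and (a1 == a2).all()
        assert not (np.isnan(d1).any() or np.isnan(a1).any())


class TestPooling:
    def test_worked_example(self):
        res = pool([0.4, 0.6], [0.01, 0.01])
        assert res.qbar == pytest.approx(0.5)
        assert res.w == pytest.approx(0.01)
        assert res.b == pytest.approx(0.02)
        assert res.t == pytest.approx(0.04)
        assert res.se == pytest.approx(0.2)

    def test_identical_imputations_give_zero_fmi(self):
        res = pool([0.5, 0.5, 0.5], [0.01, 0.01, 0.01])
        assert res.b == 0.0
        assert res.t == res.w
        assert res.fmi == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pool([0.4], [0.01])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.001, 1)),
                    min_size=2, max_size=30))
    def test_total_variance_identity(self, pairs):
        q = [p[0] for p in pairs]
        u = [p[1] for p in pairs]
        res = pool(q, u)
        assert res.t == pytest.approx(res.w + (1 + 1 / res.m) * res.b, rel=1e-12)
        assert 0.0 <= res.fmi <= 1.0


class TestMiEstimate:
    def test_no_missing_data_coincides_with_complete_case(self):
        spec = ScenarioSpec(n=5000, seed=8)
        cohort = draw_cohort(spec, rng_stream(spec.seed, 0, 0))
        pooled = mi_estimate(cohort, 5, rng_stream(spec.seed, 0, 3))
        cc = complete_case_estimate(cohort)
        assert pooled.qbar == cc.estimate
        assert pooled.b == 0.0

    def test_pooled_output_consistent(self):
        spec = ScenarioSpec(n=10_000, factor1=0.4, factor3=True, seed=8)
        cohort = simulate_replicate(spec, 0)
        pooled = mi_estimate(cohort, 10, rng_stream(spec.seed, 0, 3))
        assert pooled.m == 10
        assert pooled.t == pytest.approx(pooled.w + (1 + 0.1) * pooled.b, rel=1e-12)
        assert 0.0 < pooled.fmi < 1.0
        assert pooled.n_failed == 0

    def test_bootstrap_draw_supported(self):
        spec = ScenarioSpec(n=10_000, factor1=0.4, seed=8)
        cohort = simulate_replicate(spec, 0)
        pooled = mi_estimate(cohort, 4, rng_stream(spec.seed, 0, 3), draw="bootstrap")
        assert math.isfinite(pooled.qbar)
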