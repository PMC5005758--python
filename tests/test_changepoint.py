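import numpy as np
import pytest
import scipy.optimize
import statsmodels.api as sm

from _oracles import naive_log_posterior, sort_based_quantile
from conftest import make_series
from cpdid.changepoint import (
    ChangepointParams,
    McmcConfig,
    PriorSpec,
    log_mean,
    log_posterior,
    percent_change_per_quarter,
    sample_posterior,
    step_indicator,
    summarize_posterior,
)


@pytest.mark.parametrize(
    "t, tau, expected", [(30, 30.5, 0), (31, 30.5, 1), (30.5, 30.5, 1), (1, 40, 0)]
)
def test_step_indicator_inclusive_at_tau(t, tau, expected):
    assert step_indicator(t, tau) == expected


class TestLogMean:
    def test_model1_pre_change_ignores_shift_terms(self):
        p = ChangepointParams(tau=30.5, beta0=1.25, beta1=0.03, beta2=-1.68, beta3=0.04)
        assert log_mean(29, p, 0.0, model=1) == pytest.approx(1.25 + 0.03 * 29)

    def test_model2_post_change_intercept(self):
        p = ChangepointParams(tau=10.5, beta0=4.79, beta2=-0.29)
        assert log_mean(20, p, 0.0, model=2) == pytest.approx(4.50)

    def test_model1_post_change_full_formula(self):
        p = ChangepointParams(tau=30.5, beta0=1.25, beta1=0.03, beta2=-1.68, beta3=0.04)
        t = 35
        expected = 1.25 - 1.68 + 0.03 * t + 0.04 * (t - 30.5) + 0.7
        assert log_mean(t, p, 0.7, model=1) == pytest.approx(expected)

    def test_model2_reduces_model1_with_zero_slopes(self):
        # the level-shift model is the b1 = b3 = 0 special case
        p2 = ChangepointParams(tau=12.3, beta0=0.5, beta2=-0.8)
        p1 = ChangepointParams(tau=12.3, beta0=0.5, beta1=0.0, beta2=-0.8, beta3=0.0)
        for t in np.linspace(1, 40, 17):
            assert log_mean(t, p2, 0.2, model=2) == log_mean(t, p1, 0.2, model=1)


class TestLogPosterior:
    def test_out_of_support_tau_is_minus_inf(self):
        s = make_series([1, 2, 3, 4])
        p = ChangepointParams(tau=50.0, beta0=0.0)
        assert log_posterior(p, s, PriorSpec(tau_low=1, tau_high=40)) == -np.inf

    def test_single_zero_count_contribution(self):
        # Poisson pmf at zero contributes exactly -exp(log-mean)
        s1 = make_series([0], O=[2.0])
        prior = PriorSpec()
        p = ChangepointParams(tau=1.0, beta0=0.3, beta1=0.1, beta2=-0.2, beta3=0.05)
        m = log_mean(1, p, np.log(2.0), model=1)
        prior_part = log_posterior(p, s1, prior) + np.exp(m)
        # removing the likelihood leaves only the prior terms
        assert prior_part == pytest.approx(naive_log_posterior(p, s1, prior, 1) + np.exp(m))

    @pytest.mark.parametrize("model", [1, 2])
    def test_matches_naive_oracle(self, model, rng):
        prior = PriorSpec()
        for _ in range(25):
            n = int(rng.integers(3, 41))
            s = make_series(rng.poisson(5.0, n), O=rng.uniform(0.5, 3.0, n))
            p = ChangepointParams(
                tau=float(rng.uniform(-5, 45)),
                beta0=float(rng.normal(0, 1)),
                beta1=float(rng.normal(0, 0.05)),
                beta2=float(rng.normal(0, 1)),
                beta3=float(rng.normal(0, 0.05)),
            )
            mine = log_posterior(p, s, prior, model=model)
            ref = naive_log_posterior(p, s, prior, model)
            if np.isinf(ref):
                assert np.isinf(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-10)

    def test_flat_prior_mode_matches_poisson_glm(self, rng):
        # with the step disabled (tau past the data) the posterior mode of
        # (b0, b1) agrees with the ML log-linear Poisson fit
        n = 40
        t = np.arange(1, n + 1)
        O = rng.uniform(1.0, 2.0, n)
        y = rng.poisson(np.exp(0.8 + 0.03 * t) * O)
        s = make_series(y, O=O)
        prior = PriorSpec(tau_low=1, tau_high=100)

        def neg(lp_args):
            b0, b1 = lp_args
            p = ChangepointParams(tau=90.0, beta0=b0, beta1=b1, beta2=0.0, beta3=0.0)
            return -log_posterior(p, s, prior, model=1)

        opt = scipy.optimize.minimize(neg, [0.0, 0.0], method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        X = np.column_stack([np.ones(n), t])
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(O)).fit()
        np.testing.assert_allclose(opt.x, glm.params, atol=5e-4)


class TestSampler:
    def test_identical_seeds_identical_chains(self):
        s = make_series([3, 4, 5, 2, 1, 0, 2, 3], O=np.ones(8))
        cfg = McmcConfig(n_iter=400, n_burnin=100, seed=5,
                         proposal_sds={"tau": 1.0, "beta0": 0.2, "beta2": 0.2})
        prior = PriorSpec(tau_low=1, tau_high=8)
        a = sample_posterior(s, prior, cfg, model=2)
        b = sample_posterior(s, prior, cfg, model=2)
        for name in a.param_names:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_prior_only_recovers_prior(self):
        cfg = McmcConfig(n_iter=8000, n_burnin=2000, seed=17)
        ch = sample_posterior(None, PriorSpec(), cfg, model=1, prior_only=True)
        tau = ch.pooled("tau")
        assert tau.mean() == pytest.approx(20.5, abs=1.0)
        assert tau.min() >= 1.0 and tau.max() <= 40.0
        b = ch.pooled("beta0")
        assert abs(b.mean()) < 200
        assert 650 < b.std() < 1350

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(None, model=1)

    def test_all_zero_counts_warns_weak_identification(self):
        s = make_series(np.zeros(10, dtype=int), O=np.ones(10))
        cfg = McmcConfig(n_iter=200, n_burnin=50, seed=1)
        with pytest.warns(UserWarning, match="weakly identified"):
            sample_posterior(s, PriorSpec(tau_low=1, tau_high=10), cfg, model=2)

    def test_acceptance_rates_reported_in_unit_interval(self):
        s = make_series([5, 6, 4, 7, 2, 1, 2, 1], O=np.ones(8))
        cfg = McmcConfig(n_iter=600, n_burnin=200, seed=2)
        ch = sample_posterior(s, PriorSpec(tau_low=1, tau_high=8), cfg, model=2)
        for name, rates in ch.acceptance.items():
            assert rates.shape == (3,)
            assert np.all((rates >= 0) & (rates <= 1))
            assert np.any(rates > 0)

    def test_model2_posterior_invariant_to_model1_constrained_likelihood(self):
        # identical likelihood surface: model-2 log posterior differs from
        # the b1=b3=0 model-1 one by a constant (the two extra prior terms)
        s = make_series([8, 9, 11, 2, 1, 2], O=np.ones(6))
        prior = PriorSpec(tau_low=1, tau_high=6)
        pts = [(2.1, 0.4, -1.0), (3.7, 1.2, -0.3), (5.5, -0.2, 0.8)]
        diffs = []
        for tau, b0, b2 in pts:
            lp2 = log_posterior(ChangepointParams(tau=tau, beta0=b0, beta2=b2),
                                s, prior, model=2)
            lp1 = log_posterior(
                ChangepointParams(tau=tau, beta0=b0, beta1=0.0, beta2=b2, beta3=0.0),
                s, prior, model=1)
            diffs.append(lp1 - lp2)
        assert np.ptp(diffs) < 1e-10

    def test_level_shift_recovery_model2(self):
        from cpdid.synthetic import SimulationConfig, simulate_quarterly_counts

        sim = simulate_quarterly_counts(
            SimulationConfig(tau_true=10.5, betas_true=(4.79, -0.29),
                             pop_2000=1_290_000, pop_2010=1_180_000,
                             offset_scale=1_250_000, seed=4,
                             group_label="non-SRTS")
        )
        ch = sample_posterior(sim.series, config=McmcConfig(seed=9), model=2)
        summ = summarize_posterior(ch)
        assert summ.loc["tau", "mean"] == pytest.approx(10.5, abs=1.0)
        assert summ.loc["beta0", "mean"] == pytest.approx(4.79, abs=0.1)
        assert summ.loc["beta0+beta2", "mean"] == pytest.approx(4.50, abs=0.1)


class TestSummaries:
    def _chains_from(self, values):
        from cpdid.changepoint import PosteriorChains

        arr = np.asarray(values, dtype=float)[None, :]
        return PosteriorChains(
            draws={"x": arr}, acceptance={"x": np.array([0.3])},
            model=2, prior=PriorSpec(), config=McmcConfig(n_iter=2, n_burnin=0, seed=0),
        )

    def test_constant_chain(self):
        s = summarize_posterior(self._chains_from([3.3] * 10), derived={})
        assert s.loc["x", "mean"] == 3.3
        assert s.loc["x", "ci_low"] == s.loc["x", "ci_high"] == 3.3

    def test_quantiles_match_sort_based_oracle(self):
        vals = np.arange(1.0, 101.0)
        s = summarize_posterior(self._chains_from(vals), derived={})
        assert s.loc["x", "mean"] == pytest.approx(50.5)
        assert s.loc["x", "ci_low"] == pytest.approx(sort_based_quantile(vals, 0.025))
        assert s.loc["x", "ci_high"] == pytest.approx(sort_based_quantile(vals, 0.975))

    def test_derived_exponential_of_post_intercept(self):
        s = summarize_posterior(
            self._chains_from([4.50] * 20),
            derived={"exp(x)": lambda d: np.exp(d["x"])},
        )
        assert round(s.loc["exp(x)", "mean"], 2) == 90.02

    def test_derived_transform_is_per_draw_not_of_the_mean(self):
        pct = percent_change_per_quarter(np.array([0.02, 0.05]))
        expected = ((np.exp(0.02) - 1) + (np.exp(0.05) - 1)) / 2
        assert pct["mean"] == pytest.approx(expected)
        assert pct["mean"] != pytest.approx(np.exp(0.035) - 1, abs=1e-6)

    def test_percent_change_examples(self):
        assert percent_change_per_quarter(np.full(5, 0.03))["mean"] == pytest.approx(
            0.030455, abs=1e-5
        )
        assert percent_change_per_quarter(np.zeros(5))["mean"] == 0.0
        with pytest.raises(ValueError):
            percent_change_per_quarter(np.array([np.nan]))

    def test_empty_chains_rejected(self):
        from cpdid.changepoint import PosteriorChains

        empty = PosteriorChains(
            draws={"x": np.empty((1, 0))}, acceptance={"x": np.array([0.0])},
            model=2, prior=PriorSpec(), config=McmcConfig(n_iter=2, n_burnin=0, seed=0),
        )
        with pytest.raises(ValueError):
            summarize_posterior(empty)
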