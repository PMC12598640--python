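"""Mixture cure MLE: likelihood oracles, gradient, recovery, predictions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit, logit

from cureaudit import (
    CureDesign,
    DegenerateDataError,
    FitOptions,
    ScenarioConfig,
    apply_admin_censoring,
    cure_loglik,
    cure_loglik_grad,
    fit_mixture_cure,
    generate_cohort,
    group_indicator,
    population_survival,
    predict_incidence,
)

I_ONLY = CureDesign()                       # intercept-only both components
GROUP = CureDesign(("group2",), ("group2",))


def censored_lognormal_loglik(params, t, d, X):
    """Independent oracle: censored log-normal log-likelihood via
    scipy.stats.lognorm (a different code path than the package's)."""
    beta, sigma = np.asarray(params[:-1]), params[-1]
    scale = np.exp(X @ beta)
    return float(np.sum(np.where(d == 1,
                                 stats.lognorm.logpdf(t, s=sigma, scale=scale),
                                 stats.lognorm.logsf(t, s=sigma, scale=scale))))


class TestLoglik:
    def test_hand_evaluated_censored_term(self, toy_cohort):
        # pi = 0.5 (gamma0 = 0); S(t|x) = 0.8 at t = 1 needs beta0 s.t.
        # Phi(-(0 - beta0)/sigma) = 0.8 with sigma = 1
        beta0 = stats.norm.ppf(0.8)
        c = toy_cohort([1.0], [0])
        val = cure_loglik(np.array([0.0, beta0, 0.0]), c, I_ONLY)
        assert val == pytest.approx(np.log(0.5 + 0.5 * 0.8), abs=1e-10)

    def test_event_with_zero_incidence_is_guarded(self, toy_cohort):
        c = toy_cohort([1.0], [1])
        val = cure_loglik(np.array([-500.0, 0.0, 0.0]), c, I_ONLY)
        assert np.isfinite(val) and val < -100

    def test_reduction_to_censored_lognormal(self, toy_cohort):
        # with pi == 1 the cure likelihood IS the censored log-normal one
        rng = np.random.default_rng(0)
        t = rng.lognormal(np.log(4), 0.5, 60)
        d = rng.integers(0, 2, 60)
        d[0], d[1] = 1, 0
        c = toy_cohort(t, d)
        X = np.ones((60, 1))
        for beta0, sigma in [(np.log(4), 0.5), (1.0, 1.3), (2.0, 0.25)]:
            ours = cure_loglik(np.array([40.0, beta0, np.log(sigma)]), c, I_ONLY)
            oracle = censored_lognormal_loglik(np.array([beta0, sigma]), t, d, X)
            assert ours == pytest.approx(oracle, rel=1e-4)

    def test_rejects_nonpositive_times_and_nan_covariates(self, toy_cohort):
        c = toy_cohort([1.0, -1.0], [1, 0])
        with pytest.raises(ValueError, match="positive"):
            cure_loglik(np.zeros(3), c, I_ONLY)
        c = toy_cohort([1.0, 2.0], [1, 0], groups=[1, 2])
        c.loc[0, "group2"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cure_loglik(np.zeros(5), c, GROUP)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_analytic_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ScenarioConfig(n_subjects=120, median_time_g2=6.0, seed=13)
        c = group_indicator(apply_admin_censoring(generate_cohort(cfg, 0), 8.0))
        p = rng.normal(0, 1, 5) * np.array([1.5, 1.0, 0.8, 0.5, 0.4])
        g_an = cure_loglik_grad(p, c, GROUP)
        eps = 1e-5
        g_num = np.empty_like(g_an)
        for i in range(len(p)):
            e = np.zeros(len(p)); e[i] = eps
            g_num[i] = (cure_loglik(p + e, c, GROUP)
                        - cure_loglik(p - e, c, GROUP)) / (2 * eps)
        denom = max(np.max(np.abs(g_num)), 1.0)
        assert np.max(np.abs(g_an - g_num)) / denom < 1e-5


class TestFit:
    def test_tiny_data_mle_matches_grid_search(self, toy_cohort):
        # brute-force lattice over (gamma0, beta0, log sigma), evaluated
        # with an independently coded likelihood built on scipy.stats
        rng = np.random.default_rng(21)
        sus = rng.random(30) < 0.5
        t_true = np.where(sus, np.exp(rng.normal(np.log(3), 0.5, 30)), np.inf)
        cens = rng.uniform(0, 10, 30)
        t = np.minimum(t_true, cens)
        d = (t_true <= cens).astype(int)
        c = toy_cohort(t, d)
        fit = fit_mixture_cure(c, I_ONLY, FitOptions(seed=1))

        g0 = np.linspace(-3, 3, 41)[:, None, None, None]
        b0 = np.linspace(-0.5, 2.5, 41)[None, :, None, None]
        ls = np.linspace(-1.8, 0.7, 41)[None, None, :, None]
        pi = expit(g0)
        logpdf = stats.norm.logpdf(np.log(t), loc=b0, scale=np.exp(ls)) - np.log(t)
        cdf = stats.norm.cdf(np.log(t), loc=b0, scale=np.exp(ls))
        grid_ll = np.sum(np.where(d == 1, np.log(pi) + logpdf,
                                  np.log1p(-pi * cdf)), axis=-1)
        best = grid_ll.max()
        assert fit.loglik >= best - 1e-8
        assert fit.loglik - best < 0.05  # within lattice resolution

    def test_parameter_recovery_generous_followup(self, well_followed_cohort):
        fit = fit_mixture_cure(well_followed_cohort, GROUP, FitOptions(seed=2))
        assert fit.converged
        truth = np.array([logit(0.25), 0.0, np.log(4.0), 0.0, np.log(0.5)])
        se = fit.standard_errors()
        assert se is not None
        assert np.all(np.abs(fit.params - truth) < 3 * se)

    def test_complete_data_gamma_agrees_with_latent_logistic(self):
        # when every susceptible subject's event is observed, the cure
        # model's incidence must agree with a logistic fit on the latent
        # susceptibility labels themselves
        import statsmodels.api as sm

        cfg = ScenarioConfig(n_subjects=10_000, censor_upper=200.0,
                             admin_censor_times=(200.0,), seed=8)
        c = group_indicator(generate_cohort(cfg, 0))
        assert (c["event"] == c["susceptible"]).mean() > 0.99
        fit = fit_mixture_cure(c, GROUP, FitOptions(seed=3))
        Z = sm.add_constant(c[["group2"]].to_numpy())
        latent = sm.Logit(c["susceptible"].astype(float), Z).fit(disp=0)
        assert np.allclose(fit.gamma, latent.params, atol=0.05)

    def test_loglik_at_optimum_beats_every_start(self, toy_cohort):
        rng = np.random.default_rng(4)
        t = rng.lognormal(1, 0.6, 200)
        d = (rng.random(200) < 0.5).astype(int)
        fit = fit_mixture_cure(toy_cohort(t, d), I_ONLY, FitOptions(seed=4))
        assert fit.loglik >= max(fit.start_logliks) - 1e-9

    def test_start_robustness_on_well_conditioned_data(self, well_followed_cohort):
        fit = fit_mixture_cure(well_followed_cohort, GROUP,
                               FitOptions(seed=5, n_restarts=4))
        assert np.max(fit.start_logliks) - np.min(fit.start_logliks) < 1e-5

    def test_zero_events_is_degenerate(self, toy_cohort):
        with pytest.raises(DegenerateDataError, match="no events"):
            fit_mixture_cure(toy_cohort([1.0, 2.0], [0, 0]), I_ONLY)

    def test_all_events_is_degenerate(self, toy_cohort):
        with pytest.raises(DegenerateDataError, match="censored"):
            fit_mixture_cure(toy_cohort([1.0, 2.0], [1, 1]), I_ONLY)


class TestPredictions:
    def test_incidence_near_truth_in_both_groups(self, well_followed_cohort):
        fit = fit_mixture_cure(well_followed_cohort, GROUP, FitOptions(seed=6))
        pi = predict_incidence(fit, pd.DataFrame({"group2": [0.0, 1.0]}))
        assert np.allclose(pi, 0.25, atol=0.02)

    def test_zero_gamma_gives_half(self, well_followed_cohort):
        fit = fit_mixture_cure(well_followed_cohort, GROUP, FitOptions(seed=6))
        fit.gamma[:] = 0.0
        pi = predict_incidence(fit, pd.DataFrame({"group2": [0.0, 1.0]}))
        assert np.allclose(pi, 0.5)

    def test_refuses_unconverged_fit(self, well_followed_cohort):
        fit = fit_mixture_cure(well_followed_cohort, GROUP, FitOptions(seed=6))
        fit.converged = False
        with pytest.raises(RuntimeError, match="unconverged"):
            predict_incidence(fit, pd.DataFrame({"group2": [0.0]}))

    def test_incidence_stable_across_cutoffs(self):
        # the incidence prediction is horizon-free: refitting after an
        # earlier cutoff stays near truth, with more variance
        cfg = ScenarioConfig(n_subjects=10_000, median_time_g2=4.0, seed=10)
        base = group_indicator(generate_cohort(cfg, 0))
        for cutoff in (6.0, 12.0):
            fit = fit_mixture_cure(apply_admin_censoring(base, cutoff), GROUP,
                                   FitOptions(seed=7))
            pi = predict_incidence(fit, pd.DataFrame({"group2": [0.0, 1.0]}))
            assert np.allclose(pi, 0.25, atol=0.04)


@pytest.fixture(scope="module")
def well_followed_fit(well_followed_cohort):
    return fit_mixture_cure(well_followed_cohort, GROUP, FitOptions(seed=8))


class TestPopulationSurvival:
    def test_limits_and_plateau(self, well_followed_fit):
        fit = well_followed_fit
        row = pd.DataFrame({"group2": [0.0]})
        pi = predict_incidence(fit, row)[0]
        assert population_survival(1e-9 + 1e-12, row, fit)[0] == pytest.approx(1.0, abs=1e-6)
        assert population_survival(1e9, row, fit)[0] == pytest.approx(1 - pi, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 50.0), st.floats(0.01, 50.0))
    def test_nonincreasing_and_bounded_below(self, well_followed_fit, t1, t2):
        fit = well_followed_fit
        row = pd.DataFrame({"group2": [1.0]})
        lo, hi = sorted([t1, t2])
        s_lo = population_survival(lo, row, fit)[0]
        s_hi = population_survival(hi, row, fit)[0]
        assert s_hi <= s_lo + 1e-12
        pi = predict_incidence(fit, row)[0]
        assert 1 - pi - 1e-12 <= s_hi <= 1 + 1e-12

    def test_rejects_nonpositive_time(self, well_followed_fit):
        with pytest.raises(ValueError):
            population_survival(0.0, pd.DataFrame({"group2": [0.0]}), well_followed_fit)

    def test_pi_one_reduces_to_lognormal_survival(self, well_followed_fit):
        import copy

        fit = copy.deepcopy(well_followed_fit)
        fit.gamma[:] = [40.0, 0.0]
        row = pd.DataFrame({"group2": [0.0]})
        t = 4.0
        expected = stats.lognorm.sf(t, s=fit.sigma, scale=np.exp(fit.beta[0]))
        assert population_survival(t, row, fit)[0] == pytest.approx(expected, rel=1e-10)
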