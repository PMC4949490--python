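import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logsumexp
from scipy.stats import multivariate_normal

from spiralmix.data_model import CohortData
from spiralmix.spiral_mcmc import (GroupHyperparameters, MCMCConfig,
                                   SpiralState, log_marginal,
                                   piecewise_design, run_spiral_mcmc,
                                   run_spiral_mcmc_t, sample_coefficients,
                                   sample_spiral_state, state_log_probs,
                                   update_delta, update_hypers)
from spiralmix.synthetic_data import GeneratorConfig, generate_cohort

from _oracles import (quad_log_marginal_nospiral, quad_log_marginal_spiral,
                      rejection_truncated_posterior)


def strong_signal_cohort(seed):
    """Cohort with unmistakable spirals: |beta2| ~ 4, sigma = 3."""
    cfg = GeneratorConfig(mu_beta2=(-4.0, -4.0), tau_beta2=0.5, sigma=3.0,
                          seed=seed)
    return generate_cohort(cfg)


class TestPiecewiseDesign:
    def test_mean_value_after_cut(self):
        X = piecewise_design(4, 12)
        theta = np.array([100.0, 2.0, -3.0])
        # t = 6: 100 + 4*(2-(-3)) + (-3)*6 = 102
        assert X[5] @ theta == pytest.approx(102.0)

    def test_continuity_at_cut(self):
        for c in range(1, 11):
            X = piecewise_design(c, 12)
            theta = np.array([50.0, 1.3, -2.1])
            pre = theta[0] + theta[1] * c                  # first segment at t=c
            assert X[c - 1] @ theta == pytest.approx(pre)

    def test_cut_at_first_trial_is_all_post_spiral(self):
        X = piecewise_design(1, 12)
        assert np.all(X[:, 1] == 1.0)
        assert np.array_equal(X[:, 2], np.arange(12, dtype=float))

    def test_out_of_range_cut_rejected(self):
        with pytest.raises(ValueError):
            piecewise_design(0, 12)
        with pytest.raises(ValueError):
            piecewise_design(11, 12)


class TestLogMarginal:
    def test_negligible_truncation_matches_unconstrained_marginal(self):
        # prior means 20 sds inside the constraint region
        hyp = GroupHyperparameters(
            mu_alpha=100.0, tau_alpha2=9.0,
            mu_beta1=np.array([2.0, 2.0]), tau_beta12=0.01,
            mu_beta2=np.array([-3.0, -3.0]), tau_beta22=0.0225,
            sigma2=1.0, delta=np.zeros(2))
        t = np.arange(1, 13)
        y = 100 + 2 * np.minimum(t, 5) - 3 * np.maximum(t - 5, 0)
        X = piecewise_design(5, 12)
        m = np.array([100.0, 2.0, -3.0])
        D = np.diag([9.0, 0.01, 0.0225])
        ref = multivariate_normal.logpdf(y, X @ m, np.eye(12) + X @ D @ X.T)
        assert log_marginal(y, SpiralState(1, 5), hyp, 0) == pytest.approx(
            ref, abs=1e-6)

    def test_point_mass_prior_limit(self):
        # tau -> 0: marginal -> product of normal densities at the fixed
        # mean; eps trades off limit error against float cancellation in
        # the m' D^-1 m term, which scales like 1/eps
        eps = 1e-8
        hyp = GroupHyperparameters(
            mu_alpha=100.0, tau_alpha2=eps,
            mu_beta1=np.array([2.0, 2.0]), tau_beta12=eps,
            mu_beta2=np.array([-3.0, -3.0]), tau_beta22=eps,
            sigma2=4.0, delta=np.zeros(2))
        rng = np.random.default_rng(0)
        t = np.arange(1, 13)
        y = 100 + 2 * np.minimum(t, 5) - 3 * np.maximum(t - 5, 0) + rng.normal(0, 2, 12)
        mean = 100 + 2 * np.minimum(t, 5) - 3 * np.maximum(t - 5, 0)
        ref = stats.norm.logpdf(y, mean, 2.0).sum()
        assert log_marginal(y, SpiralState(1, 5), hyp, 0) == pytest.approx(
            ref, abs=1e-3)

    def test_matches_quadrature_on_toy_series(self, default_hypers, rng):
        y = 100 + 2 * np.arange(1, 5) + rng.normal(0, 2, 4)
        for c in (1, 2):
            lm = log_marginal(y, SpiralState(1, c), default_hypers, 0)
            lo = quad_log_marginal_spiral(y, c, default_hypers, 0)
            assert lm == pytest.approx(lo, abs=1e-4)
        lm0 = log_marginal(y, SpiralState(0), default_hypers, 0)
        lo0 = quad_log_marginal_nospiral(y, default_hypers, 0)
        assert lm0 == pytest.approx(lo0, abs=1e-4)


class TestSampleSpiralState:
    def test_zero_propensity_never_spirals(self, default_hypers, rng):
        hyp = default_hypers
        hyp.delta = np.array([-800.0, -800.0])  # pi = 0 numerically
        y = 100 + 2 * np.arange(1, 13.0)
        for _ in range(50):
            assert sample_spiral_state(y, hyp, 0, rng).S == 0

    def test_state_masses_normalize(self, default_hypers, rng):
        y = 100 + rng.normal(0, 5, 12)
        logp = state_log_probs(y, default_hypers, 1)
        assert logsumexp(logp) == pytest.approx(0.0, abs=1e-10)
        assert logp.size == 11  # no-spiral + 10 cut-points at T = 12

    def test_certain_spiral_moves_all_mass_off_no_spiral(self, default_hypers):
        hyp = default_hypers
        hyp.delta = np.array([800.0, 800.0])  # pi = 1 numerically
        y = 100 + np.random.default_rng(1).normal(0, 5, 12)
        logp = state_log_probs(y, hyp, 0)
        assert logp[0] < -500
        assert logsumexp(logp[1:]) == pytest.approx(0.0, abs=1e-8)

    def test_empirical_frequencies_match_enumeration(self, default_hypers, rng):
        """Chi-squared check of the exact discrete conditional at T = 4."""
        y = np.array([101.0, 103.5, 102.0, 99.0])
        probs = np.exp(state_log_probs(y, default_hypers, 0))
        n = 20_000
        counts = np.zeros(3)
        for _ in range(n):
            s = sample_spiral_state(y, default_hypers, 0, rng)
            counts[0 if s.S == 0 else s.c] += 1
        chi2 = np.sum((counts - n * probs) ** 2 / (n * probs))
        assert chi2 < stats.chi2.ppf(0.99, df=2)


class TestSampleCoefficients:
    def test_sign_constraints_hold_surely(self, default_hypers, rng):
        y = 100 + 2 * np.arange(1, 13.0) + rng.normal(0, 3, 12)
        cur = None
        for _ in range(500):
            a, b1, b2 = sample_coefficients(y, SpiralState(1, 6),
                                            default_hypers, 0, rng,
                                            current=cur, n_scans=1)
            cur = (a, b1, b2)
            assert b1 > 0 and b2 < 0

    def test_no_spiral_pins_beta2_at_zero(self, default_hypers, rng):
        y = 100 + 2 * np.arange(1, 13.0)
        for _ in range(20):
            _, b1, b2 = sample_coefficients(y, SpiralState(0),
                                            default_hypers, 0, rng)
            assert b2 == 0.0
            assert b1 > 0

    def test_chained_draws_match_rejection_oracle(self, default_hypers, rng):
        y = (100 + 2 * np.minimum(np.arange(1, 13), 5)
             - 1.0 * np.maximum(np.arange(1, 13) - 5, 0)
             + rng.normal(0, 2, 12))
        oracle = rejection_truncated_posterior(y, 5, default_hypers, 0, rng,
                                               n_keep=20_000)
        cur, keep = None, []
        for _ in range(20_000):
            cur = sample_coefficients(y, SpiralState(1, 5), default_hypers, 0,
                                      rng, current=cur, n_scans=1)
            keep.append(cur)
        keep = np.asarray(keep)
        for k, name in [(1, "beta1"), (2, "beta2")]:
            se = oracle[:, k].std() / np.sqrt(2000)  # generous autocorr allowance
            assert keep[:, k].mean() == pytest.approx(
                oracle[:, k].mean(), abs=5 * se), name
            assert keep[:, k].std() == pytest.approx(
                oracle[:, k].std(), rel=0.1), name


class TestUpdateDelta:
    def test_empty_group_component_targets_its_prior(self, rng):
        S = np.array([1, 0, 1])
        g = np.zeros(3, dtype=int)  # nobody in group 1
        delta, draws = np.array([0.0, 0.0]), []
        for _ in range(20_000):
            delta, _ = update_delta(S, g, 4.0, rng, delta)
            draws.append(delta[1])
        draws = np.asarray(draws[2000:])
        assert draws.mean() == pytest.approx(0.0, abs=0.15)
        assert draws.std() == pytest.approx(2.0, abs=0.15)

    def test_flat_prior_limit_matches_grid_posterior(self, rng):
        # c_delta -> inf: posterior of pi is Bernoulli likelihood renormalized
        S = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        g = np.zeros(10, dtype=int)
        c_delta = 1e6
        grid = np.linspace(-12, 12, 20001)
        lp = 3 * grid - 10 * np.logaddexp(0, grid) - grid**2 / (2 * c_delta)
        w = np.exp(lp - lp.max())
        ref = float(np.sum(expit(grid) * w) / np.sum(w))
        delta, acc = np.array([0.0, 0.0]), []
        for _ in range(40_000):
            delta, _ = update_delta(S, g, c_delta, rng, delta,
                                    prop_sd=np.array([1.5, 1.5]))
            acc.append(expit(delta[0]))
        assert np.mean(acc[4000:]) == pytest.approx(ref, abs=0.01)

    def test_symmetric_counts_give_centered_difference(self, rng):
        S = np.array([1, 0, 1, 0])
        g = np.array([0, 0, 1, 1])
        delta, diffs = np.array([0.0, 0.0]), []
        for _ in range(30_000):
            delta, _ = update_delta(S, g, 4.0, rng, delta)
            diffs.append(delta[0] - delta[1])
        assert np.mean(diffs[3000:]) == pytest.approx(0.0, abs=0.2)


class TestUpdateHypers:
    def test_sigma2_conjugate_bookkeeping(self, default_hypers, tight_priors,
                                          rng):
        # zero residuals, n observations: sigma2 | rest ~ IG(a + n/2, b)
        a, b = tight_priors.sigma2
        n = 40
        draws = []
        for _ in range(6000):
            hyp = default_hypers.copy()
            update_hypers(np.array([100.0]), np.array([2.0]),
                          np.array([0.0]), np.array([0]), np.array([0]),
                          tight_priors, hyp, rng, resid_ss=0.0, n_obs=n)
            draws.append(hyp.sigma2)
        expected_mean = b / (a + n / 2 - 1)
        assert np.mean(draws) == pytest.approx(expected_mean, rel=0.05)

    def test_negligible_truncation_matches_conjugate_normal(self, tight_priors,
                                                            rng):
        # mu/tau ratios > 6: the normalizer is ~ constant and the mu_beta1
        # conditional collapses to the conjugate normal formula
        rng_local = np.random.default_rng(2)
        beta1 = rng_local.normal(3.0, 0.3, size=200)
        g = np.zeros(200, dtype=int)
        pri = tight_priors.replace(mu_beta1=(3.0, 1.0))
        hyp_draws = []
        hyp = None
        from spiralmix.spiral_mcmc import GroupHyperparameters
        hyp = GroupHyperparameters(
            mu_alpha=100.0, tau_alpha2=9.0,
            mu_beta1=np.array([3.0, 3.0]), tau_beta12=0.09,
            mu_beta2=np.array([-3.0, -3.0]), tau_beta22=0.09,
            sigma2=4.0, delta=np.zeros(2))
        for _ in range(20_000):
            hyp.tau_beta12 = 0.09  # hold the scale fixed for the check
            update_hypers(np.full(200, 100.0), beta1,
                          np.full(200, -3.0), np.zeros(200, dtype=int), g,
                          pri, hyp, rng, resid_ss=1.0, n_obs=10,
                          prop_sd={"mu_beta1_0": 0.05})
            hyp_draws.append(hyp.mu_beta1[0])
        prec = 200 / 0.09 + 1.0
        mean = (beta1.sum() / 0.09 + 3.0) / prec
        draws = np.asarray(hyp_draws[2000:])
        assert draws.mean() == pytest.approx(mean, abs=0.01)
        assert draws.std() == pytest.approx(1 / np.sqrt(prec), rel=0.15)


class TestRunSpiralMcmc:
    def test_same_seed_identical_draws(self, small_cohort, tight_priors):
        cfg = MCMCConfig(n_iter=300, burn_in=100, thin=1, seed=3)
        a = run_spiral_mcmc(small_cohort, tight_priors, cfg)
        b = run_spiral_mcmc(small_cohort, tight_priors, cfg)
        assert np.array_equal(a.S, b.S)
        assert np.array_equal(a.mu_beta1, b.mu_beta1)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_every_retained_draw_satisfies_constraints(self, tight_priors):
        cohort, _ = strong_signal_cohort(21)
        cfg = MCMCConfig(n_iter=800, burn_in=200, thin=1, seed=4)
        dr = run_spiral_mcmc(cohort, tight_priors, cfg)
        assert np.all(dr.beta1 > 0)
        spiral = dr.S == 1
        assert np.all(dr.beta2[spiral] < 0)
        assert np.all(dr.beta2[~spiral] == 0.0)
        assert np.all((dr.c[spiral] >= 1) & (dr.c[spiral] <= 10))
        assert np.all(dr.c[~spiral] == 0)

    def test_strong_signal_classification(self, tight_priors):
        cohort, truth = strong_signal_cohort(5)
        cfg = MCMCConfig(n_iter=1500, burn_in=500, thin=1, seed=6)
        dr = run_spiral_mcmc(cohort, tight_priors, cfg)
        pr = dr.S.mean(axis=0)
        early = truth.c <= cohort.n_trials - 3
        assert np.all(pr[(truth.S == 1) & early] > 0.7)
        assert np.all(pr[truth.S == 0] < 0.4)

    def test_pinned_zero_propensity_reduces_to_no_spiral_model(self,
                                                               tight_priors):
        # strongly rising cohort: truncation negligible, so the spiral
        # sampler with pi = 0 must agree with the baseline conjugate Gibbs
        from spiralmix.baseline_lcm import gibbs_lcm
        cfg_gen = GeneratorConfig(pi=(0.0, 0.0), mu_beta1=(3.0, 3.0),
                                  tau_beta1=0.5, seed=13)
        cohort, _ = generate_cohort(cfg_gen)
        pri = tight_priors.replace(mu_beta1=(3.0, 1.0), mu_beta=(3.0, 1.0))
        cfg = MCMCConfig(n_iter=4000, burn_in=1000, thin=1, seed=7,
                         fix_pi=(0.0, 0.0))
        sp = run_spiral_mcmc(cohort, pri, cfg)
        assert np.all(sp.S == 0)
        base = gibbs_lcm(cohort, pri, n_iter=4000, burn_in=1000, seed=8)
        assert sp.mu_beta1[:, 0].mean() == pytest.approx(
            base.mu_E.mean(), abs=0.15)
        assert sp.mu_beta1[:, 1].mean() == pytest.approx(
            base.mu_I.mean(), abs=0.15)

    def test_group_label_exchange_swaps_posteriors(self, tight_priors):
        cohort, _ = strong_signal_cohort(9)
        swapped = CohortData(
            individual_ids=cohort.individual_ids,
            groups=["incremental" if g == "entity" else "entity"
                    for g in cohort.groups],
            scores=cohort.scores)
        cfg = MCMCConfig(n_iter=2500, burn_in=500, thin=1, seed=10)
        a = run_spiral_mcmc(cohort, tight_priors, cfg)
        b = run_spiral_mcmc(swapped, tight_priors, cfg)
        pa, pb = a.pi.mean(axis=0), b.pi.mean(axis=0)
        assert pa[0] == pytest.approx(pb[1], abs=0.1)
        assert pa[1] == pytest.approx(pb[0], abs=0.1)


class TestStudentTVariant:
    def test_scale_mixture_identity(self, rng):
        # lambda ~ IG(nu/2, nu/2): E[1/lambda] = 1 and z*sqrt(lambda) ~ t_nu
        nu = 5.0
        lam = 1.0 / rng.gamma(nu / 2, 2.0 / nu, size=200_000)
        assert np.mean(1.0 / lam) == pytest.approx(1.0, abs=0.01)
        draws = rng.standard_normal(200_000) * np.sqrt(lam)
        ks = stats.kstest(draws, stats.t(df=nu).cdf)
        assert ks.pvalue > 0.01

    def test_large_nu_matches_normal_sampler(self, tight_priors):
        cohort, _ = strong_signal_cohort(17)
        cfg = MCMCConfig(n_iter=1200, burn_in=400, thin=1, seed=11)
        normal = run_spiral_mcmc(cohort, tight_priors, cfg)
        heavy = run_spiral_mcmc_t(cohort, tight_priors, cfg, nu=1e6)
        pn = normal.S.mean(axis=0)
        pt = heavy.S.mean(axis=0)
        assert np.max(np.abs(pn - pt)) < 0.15

    def test_nu_validation(self, small_cohort, tight_priors):
        with pytest.raises(ValueError):
            run_spiral_mcmc_t(small_cohort, tight_priors,
                              MCMCConfig(n_iter=10, burn_in=1, seed=0), nu=2.0)
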