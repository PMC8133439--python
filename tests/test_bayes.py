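import numpy as np
import pytest
from scipy import stats

from c14growth import (
    C14Sample,
    MCMCConfig,
    PriorSpec,
    Window,
    fit_mcmc,
    hpd_interval,
    log_marginal_likelihood_date,
    pmf_exponential,
    pmf_from_trajectory,
    prior_logpdf,
    sample_latent_dates,
    simulate_dates,
)
from c14growth.bayes import precompute_likelihood
from c14growth.errors import ConfigError, InitializationError


class TestPriors:
    def test_exponential_closed_form(self):
        # rate lambda = 2500 evaluated at its mean 0.0004: log(lambda) - 1
        assert prior_logpdf(PriorSpec.exponential(2500), 0.0004) == pytest.approx(np.log(2500) - 1)
        assert prior_logpdf(PriorSpec.exponential(2500), -0.1) == -np.inf

    def test_normal_at_mean(self):
        assert prior_logpdf(PriorSpec.normal(0, 0.0004), 0.0) == pytest.approx(
            np.log(1.0 / (0.0004 * np.sqrt(2 * np.pi)))
        )

    def test_truncated_normal_outside_support(self):
        spec = PriorSpec.truncated_normal(2625, 200, 1850, 3400)
        assert prior_logpdf(spec, 1800) == -np.inf

    def test_truncated_normal_renormalised(self):
        spec = PriorSpec.truncated_normal(2625, 200, 1850, 3400)
        oracle = stats.truncnorm(
            (1850 - 2625) / 200, (3400 - 2625) / 200, loc=2625, scale=200
        ).logpdf(2700)
        assert prior_logpdf(spec, 2700) == pytest.approx(float(oracle), rel=1e-12)

    def test_uniform_and_fixed(self):
        assert prior_logpdf(PriorSpec.uniform(0, 4), 1.0) == pytest.approx(-np.log(4))
        assert prior_logpdf(PriorSpec.uniform(0, 4), 5.0) == -np.inf
        assert prior_logpdf(PriorSpec.fixed(3.0), 3.0) == 0.0
        assert not PriorSpec.fixed(3.0).is_free

    def test_invalid_spec(self):
        with pytest.raises(ConfigError):
            PriorSpec.normal(0, -1)
        with pytest.raises(ConfigError):
            PriorSpec.uniform(2, 1)


class TestMarginalLikelihood:
    def test_degenerate_pmf_single_term(self, identity_curve):
        w = Window(5010, 4990)
        traj = np.full(w.T + 1, 1e-12)
        traj[10] = 1.0  # all mass (numerically) at t = 5000
        pmf = pmf_from_trajectory(w, traj / traj.sum() * (w.T + 1))
        s = C14Sample("A", 5005.0, 20.0)
        got = log_marginal_likelihood_date(s, identity_curve, pmf)
        want = stats.norm.logpdf(5005.0, 5000.0, 20.0)
        assert got == pytest.approx(want, abs=1e-6)

    def test_matches_bruteforce_loop(self, identity_curve_tau20):
        w = Window(5015, 4986)  # 30-year toy grid
        pmf = pmf_exponential(w, 0.004)
        s = C14Sample("A", 5003.0, 17.0)
        sigma = np.sqrt(17.0**2 + 20.0**2)
        acc = 0.0
        for i, t in enumerate(range(w.a, w.b - 1, -1)):
            acc += pmf.p[i] * stats.norm.pdf(5003.0, t, sigma)
        got = log_marginal_likelihood_date(s, identity_curve_tau20, pmf)
        assert got == pytest.approx(np.log(acc), abs=1e-12)

    def test_uniform_pmf_is_log_mean_density(self, identity_curve):
        w = Window(5020, 4981)
        pmf = pmf_exponential(w, 0.0)
        s = C14Sample("A", 5000.0, 25.0)
        dens = stats.norm.pdf(5000.0, np.arange(w.a, w.b - 1, -1.0), 25.0)
        got = log_marginal_likelihood_date(s, identity_curve, pmf)
        assert got == pytest.approx(np.log(dens.mean()), abs=1e-12)


class TestLatentGibbs:
    def test_full_conditional_matches_enumeration(self, identity_curve):
        """One exact Gibbs draw of a latent date follows the enumerated
        categorical p(theta=t) ~ p_t * N(x; mu(t), sigma) (TV < 0.01)."""
        w = Window(5010, 4991)  # 20-year grid
        pmf = pmf_exponential(w, 0.01)
        s = C14Sample("A", 5002.0, 6.0)
        # enumerated conditional
        t = np.arange(w.a, w.b - 1, -1.0)
        weights = pmf.p * stats.norm.pdf(s.x, t, s.sigma_lab)
        target = weights / weights.sum()
        # 100,000 independent draws: identical rows in the cache are
        # conditionally independent updates of the same date
        cache = precompute_likelihood([s] * 10_000, identity_curve, w)
        draws = np.concatenate(
            [sample_latent_dates(pmf, cache, seed=np.random.default_rng(k)) for k in range(10)]
        )
        freq = np.bincount((w.a - draws).astype(int), minlength=w.T + 1) / len(draws)
        tv = 0.5 * np.abs(freq - target).sum()
        assert tv < 0.01


def _exp_design(curve, n=200, r=0.003, window=Window(5500, 4500), seed=11, **cfg):
    samples = simulate_dates("exponential", {"r": r}, window, n, curve, 20.0, seed=seed)
    config = MCMCConfig(
        n_chains=cfg.pop("n_chains", 1),
        n_iterations=cfg.pop("n_iterations", 4000),
        n_burnin=cfg.pop("n_burnin", 1000),
        thin=cfg.pop("thin", 2),
        seed=cfg.pop("seed", 99),
    )
    priors = {"r": PriorSpec.exponential(500)}
    return samples, config, priors, window


class TestFitMCMC:
    def test_prior_only_recovers_prior_moments(self, identity_curve):
        """With no data the chain targets the prior (detailed-balance check)."""
        w = Window(5025, 4975)
        priors = {"r": PriorSpec.normal(0.002, 0.001)}
        config = MCMCConfig(n_chains=1, n_iterations=30_000, n_burnin=2_000, thin=5, seed=4)
        post = fit_mcmc([], "exponential", w, priors, identity_curve, config)
        draws = post.flat("r")
        from c14growth import effective_sample_size

        ess = effective_sample_size(draws)
        se_mean = 0.001 / np.sqrt(ess)
        assert abs(draws.mean() - 0.002) < 3 * se_mean
        assert abs(draws.std() - 0.001) < 3 * 0.001 / np.sqrt(2 * ess)

    def test_flat_likelihood_returns_prior(self, identity_curve):
        """One nearly uninformative date: posterior ~ prior (KS < 0.05)."""
        w = Window(5100, 4900)
        s = C14Sample("A", 5000.0, 400.0)
        priors = {"r": PriorSpec.exponential(500)}
        config = MCMCConfig(n_chains=1, n_iterations=42_000, n_burnin=2_000, thin=20, seed=8)
        post = fit_mcmc([s], "exponential", w, priors, identity_curve, config)
        prior_draws = stats.expon(scale=1 / 500).rvs(size=20_000, random_state=np.random.default_rng(9))
        ks = stats.ks_2samp(post.flat("r"), prior_draws).statistic
        assert ks < 0.05

    def test_recovery_smoke_small(self, identity_curve):
        """Most small replicates cover the true rate with a 90% HPD."""
        w = Window(5500, 4500)
        covered = 0
        for rep in range(3):
            samples = simulate_dates("exponential", {"r": 0.003}, w, 100, identity_curve, 20.0, seed=100 + rep)
            config = MCMCConfig(n_chains=1, n_iterations=4000, n_burnin=1000, thin=2, seed=200 + rep)
            post = fit_mcmc(samples, "exponential", w, {"r": PriorSpec.exponential(500)}, identity_curve, config)
            if 0.003 in hpd_interval(post.flat("r"), 0.9):
                covered += 1
        assert covered >= 2

    def test_acceptance_rate_adapts_into_band(self, identity_curve):
        samples, config, priors, w = _exp_design(identity_curve)
        post = fit_mcmc(samples, "exponential", w, priors, identity_curve, config)
        rate = post.acceptance["r"][0]
        assert 0.2 <= rate <= 0.6

    def test_bitwise_reproducible(self, identity_curve):
        samples, config, priors, w = _exp_design(identity_curve, n=50, n_iterations=1500, n_burnin=500)
        a = fit_mcmc(samples, "exponential", w, priors, identity_curve, config)
        b = fit_mcmc(samples, "exponential", w, priors, identity_curve, config)
        assert np.array_equal(a.flat("r"), b.flat("r"))

    def test_latent_draws_lie_in_window(self, identity_curve):
        samples, config, priors, w = _exp_design(identity_curve, n=30, n_iterations=800, n_burnin=200)
        post = fit_mcmc(samples, "exponential", w, priors, identity_curve, config, save_latent=True)
        assert post.latent.shape[-1] == 30
        assert post.latent.min() >= w.b and post.latent.max() <= w.a

    def test_missing_prior_config_error(self, identity_curve):
        with pytest.raises(ConfigError, match="r2"):
            fit_mcmc([], "double_exponential", Window(6000, 4000), {"r1": PriorSpec.normal(0, 0.1), "c": PriorSpec.uniform(4001, 5999)}, identity_curve, MCMCConfig(n_iterations=10, n_burnin=0))

    def test_all_underflow_initialization_error(self, identity_curve):
        s = C14Sample("far", 300_000.0, 5.0)
        with pytest.raises(InitializationError):
            fit_mcmc([s], "exponential", Window(5100, 4900), {"r": PriorSpec.exponential(500)}, identity_curve, MCMCConfig(n_iterations=10, n_burnin=0))

    def test_posterior_dataframe_shape(self, identity_curve):
        samples, config, priors, w = _exp_design(identity_curve, n=30, n_iterations=1000, n_burnin=500, n_chains=2)
        post = fit_mcmc(samples, "exponential", w, priors, identity_curve, config)
        df = post.to_dataframe()
        assert set(df.columns) == {"chain", "r"}
        assert sorted(df["chain"].unique()) == [0, 1]
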