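"""Hierarchical Bayesian inference for bounded growth models.

The model: each sample's true calendar date is a draw from a bounded
growth PMF on the analysis window,

    theta_j ~ BoundedGrowth(a, b, params)
    X_j     ~ Normal(mu(theta_j), sigma_j),

where ``sigma_j`` combines the lab error and the calibration-curve error
in quadrature. The window boundaries a, b are user-set constants; the
growth parameters carry priors and are sampled by adaptive univariate
random-walk Metropolis-Hastings.

Because the latent dates are discrete on a finite grid they can be summed
out exactly: the per-date marginal likelihood is
``sum_t p_t Normal(X_j; mu(t), sigma_j(t))``. The sampler targets the
collapsed posterior of the growth parameters against this marginal
likelihood, and the latent ``theta_j`` can be drawn exactly from their
categorical full conditional at any retained draw — the joint target is
identical to alternating parameter-MH with per-date Gibbs updates, but
mixing is better and the cost per iteration is a single matrix-vector
product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .calcurve import CalCurve, grid_curve
from .caldate import C14Sample
from .errors import ConfigError, DomainError, InitializationError
from .growth import (
    GrowthPMF,
    Window,
    WindowLike,
    as_window,
    pmf_double_exponential,
    pmf_exp_logistic,
    pmf_exponential,
)

__all__ = [
    "PriorSpec",
    "prior_logpdf",
    "MCMCConfig",
    "PosteriorSamples",
    "PARAM_NAMES",
    "build_pmf",
    "precompute_likelihood",
    "log_marginal_likelihood_date",
    "marginal_loglik",
    "pointwise_loglik",
    "sample_latent_dates",
    "fit_mcmc",
]

_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)

#: Free parameters of each growth-model variant, in update order.
PARAM_NAMES = {
    "exponential": ("r",),
    "double_exponential": ("r1", "r2", "c"),
    "exp_logistic": ("r1", "r2", "c", "k"),
}


# ---------------------------------------------------------------------------
# Priors


from functools import lru_cache


@lru_cache(maxsize=None)
def _truncnorm_log_mass(params: tuple) -> float:
    mu, sigma, lo, hi = params
    return math.log(stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma))


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior: one of exponential / normal / truncated_normal /
    uniform / fixed, with the usual parameters.

    Exponential priors are parameterised by RATE (lambda), so
    ``PriorSpec.exponential(2500)`` has mean 1/2500 = 0.0004.
    """

    dist: str
    params: tuple

    # -- constructors -------------------------------------------------------
    @staticmethod
    def exponential(rate: float) -> "PriorSpec":
        if rate <= 0:
            raise ConfigError("exponential prior requires rate > 0")
        return PriorSpec("exponential", (float(rate),))

    @staticmethod
    def normal(mu: float, sigma: float) -> "PriorSpec":
        if sigma <= 0:
            raise ConfigError("normal prior requires sigma > 0")
        return PriorSpec("normal", (float(mu), float(sigma)))

    @staticmethod
    def truncated_normal(mu: float, sigma: float, lower: float, upper: float) -> "PriorSpec":
        if sigma <= 0:
            raise ConfigError("truncated normal prior requires sigma > 0")
        if not lower < upper:
            raise ConfigError("truncated normal prior requires lower < upper")
        return PriorSpec("truncated_normal", (float(mu), float(sigma), float(lower), float(upper)))

    @staticmethod
    def uniform(lower: float, upper: float) -> "PriorSpec":
        if not lower < upper:
            raise ConfigError("uniform prior requires lower < upper")
        return PriorSpec("uniform", (float(lower), float(upper)))

    @staticmethod
    def fixed(value: float) -> "PriorSpec":
        return PriorSpec("fixed", (float(value),))

    # -- behaviour ----------------------------------------------------------
    @property
    def is_free(self) -> bool:
        return self.dist != "fixed"

    def _frozen(self):
        if self.dist == "exponential":
            (rate,) = self.params
            return stats.expon(scale=1.0 / rate)
        if self.dist == "normal":
            mu, sigma = self.params
            return stats.norm(mu, sigma)
        if self.dist == "truncated_normal":
            mu, sigma, lo, hi = self.params
            return stats.truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)
        if self.dist == "uniform":
            lo, hi = self.params
            return stats.uniform(lo, hi - lo)
        raise ConfigError(f"unknown prior distribution {self.dist!r}")

    def logpdf(self, value: float) -> float:
        """Exact log density; -inf outside the support (never an error).

        Closed forms (the truncated normal renormalised by its in-bounds
        mass) — evaluated once per MCMC proposal, so no frozen-dist
        construction here.
        """
        if self.dist == "fixed":
            return 0.0 if value == self.params[0] else -np.inf
        if self.dist == "exponential":
            (rate,) = self.params
            return math.log(rate) - rate * value if value >= 0 else -np.inf
        if self.dist == "normal":
            mu, sigma = self.params
            z = (value - mu) / sigma
            return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI
        if self.dist == "truncated_normal":
            mu, sigma, lo, hi = self.params
            if not (lo <= value <= hi):
                return -np.inf
            z = (value - mu) / sigma
            return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI - _truncnorm_log_mass(self.params)
        if self.dist == "uniform":
            lo, hi = self.params
            return -math.log(hi - lo) if lo <= value <= hi else -np.inf
        raise ConfigError(f"unknown prior distribution {self.dist!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed":
            return self.params[0]
        return float(self._frozen().rvs(random_state=rng))

    @property
    def mean(self) -> float:
        if self.dist == "fixed":
            return self.params[0]
        return float(self._frozen().mean())

    @property
    def sd(self) -> float:
        if self.dist == "fixed":
            return 0.0
        return float(self._frozen().std())


def prior_logpdf(spec: PriorSpec, value: float) -> float:
    """Log prior density of ``value`` under ``spec``."""
    return spec.logpdf(value)


# ---------------------------------------------------------------------------
# Likelihood


def build_pmf(variant: str, window: WindowLike, params: dict) -> GrowthPMF:
    """Dispatch a parameter dict to the matching growth-PMF builder."""
    window = as_window(window)
    if variant == "exponential":
        return pmf_exponential(window, params["r"])
    if variant == "double_exponential":
        return pmf_double_exponential(window, params["r1"], params["r2"], params["c"])
    if variant == "exp_logistic":
        return pmf_exp_logistic(
            window, params["r1"], params["r2"], params["c"], params["k"],
            changepoint_relative=bool(params.get("changepoint_relative", False)),
        )
    raise ConfigError(f"unknown growth-model variant {variant!r}")


@dataclass(frozen=True)
class _LikelihoodCache:
    """Per-date Normal densities on the window grid, scaled per row.

    ``scaled[j, i] = exp(L[j, i] - rowmax[j])`` where
    ``L[j, i] = log Normal(x_j; mu(t_i), sigma_j(t_i))`` and ``t_i = a - i``.
    The marginal log likelihood given a PMF ``p`` is then
    ``sum_j log(scaled[j] @ p) + sum_j rowmax[j]``.
    """

    window: Window
    scaled: np.ndarray
    rowmax: np.ndarray

    @property
    def n(self) -> int:
        return self.scaled.shape[0]


def precompute_likelihood(
    samples: Sequence[C14Sample], curve: CalCurve, window: WindowLike
) -> _LikelihoodCache:
    """Precompute the (n_dates x T+1) measurement-density matrix.

    The data and curve are fixed during MCMC, so this matrix is computed
    once; every likelihood evaluation afterwards is one BLAS mat-vec.
    """
    window = as_window(window)
    g = grid_curve(curve, window.a, window.b)
    mu = g.mu[None, :]
    tau = g.tau[None, :]
    x = np.array([s.x for s in samples], dtype=float)[:, None]
    sig_lab = np.array([s.sigma_lab for s in samples], dtype=float)[:, None]
    sig = np.hypot(sig_lab, tau)
    z = (x - mu) / sig
    L = -0.5 * z * z - np.log(sig) - _LOG_SQRT_2PI
    if L.shape[0]:
        rowmax = L.max(axis=1)
        # a best log density under ~-745 means every mass underflows to 0
        if not np.all(np.isfinite(rowmax) & (rowmax >= -745.0)):
            bad = [samples[j].labcode for j in np.nonzero(~(np.isfinite(rowmax) & (rowmax >= -745.0)))[0]]
            raise InitializationError(
                f"likelihood underflows everywhere on the window for sample(s) {bad}; "
                "check the analysis window or run window_filter first"
            )
        scaled = np.exp(L - rowmax[:, None])
    else:
        rowmax = np.zeros(0)
        scaled = np.zeros((0, window.T + 1))
    return _LikelihoodCache(window, scaled, rowmax)


def log_marginal_likelihood_date(sample: C14Sample, curve: CalCurve, pmf: GrowthPMF) -> float:
    """log sum_t p_t Normal(x; mu(t), sqrt(sigma_lab^2 + tau(t)^2)).

    Computed by log-sum-exp; returns -inf when every term underflows.
    """
    g = grid_curve(curve, pmf.window.a, pmf.window.b)
    sig = np.hypot(sample.sigma_lab, g.tau)
    z = (sample.x - g.mu) / sig
    logf = -0.5 * z * z - np.log(sig) - _LOG_SQRT_2PI
    with np.errstate(divide="ignore"):
        return float(logsumexp(logf, b=pmf.p))


def marginal_loglik(cache: _LikelihoodCache, pmf: GrowthPMF) -> float:
    """Total marginal log likelihood of all cached dates under ``pmf``."""
    if cache.n == 0:
        return 0.0
    inner = cache.scaled @ pmf.p
    if np.any(inner <= 0.0):
        return -np.inf
    return float(np.log(inner).sum() + cache.rowmax.sum())


# ---------------------------------------------------------------------------
# MCMC


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``thin`` keeps every thin-th post-burn-in iteration. Adaptation
    rescales each parameter's proposal SD every ``adapt_interval``
    iterations toward ``target_acceptance`` with a Robbins-Monro decay,
    so the chain remains valid under diminishing adaptation.
    """

    n_chains: int = 1
    n_iterations: int = 10_000
    n_burnin: int = 3_000
    thin: int = 1
    seed: Optional[int] = None
    adapt_interval: int = 200
    target_acceptance: float = 0.44
    initial_scale: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ConfigError("need n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.n_chains < 1:
            raise ConfigError("n_chains must be >= 1")
        if not (0 < self.target_acceptance < 1):
            raise ConfigError("target_acceptance must lie in (0, 1)")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, organised by chain.

    ``draws[name]`` has shape (n_chains, n_draws). ``latent`` (optional)
    has shape (n_chains, n_draws, n_dates) and holds calendar years.
    """

    variant: str
    window: Window
    draws: dict
    acceptance: dict
    config: MCMCConfig
    latent: Optional[np.ndarray] = None
    param_names: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ConfigError("all parameters must have equal draw counts")
        if not self.param_names:
            self.param_names = tuple(self.draws)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[0] * first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[name].reshape(-1)

    def chains(self, name: str) -> np.ndarray:
        return self.draws[name]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw, one column per parameter plus a chain label."""
        n_chains, n_draws = next(iter(self.draws.values())).shape
        data = {"chain": np.repeat(np.arange(n_chains), n_draws)}
        for name in self.param_names:
            data[name] = self.draws[name].reshape(-1)
        return pd.DataFrame(data)

    def draw_params(self, index: int) -> dict:
        """Parameter dict of the index-th flattened draw."""
        return {name: float(self.flat(name)[index]) for name in self.param_names}


def sample_latent_dates(
    pmf: GrowthPMF, cache_or_samples, curve: Optional[CalCurve] = None, seed=None
) -> np.ndarray:
    """Draw each latent calendar date exactly from its full conditional.

    ``p(theta_j = t | params, x_j) ~ p_t * Normal(x_j; mu(t), sigma_j(t))``,
    a categorical on the window grid — one exact Gibbs update per date.
    Accepts either a precomputed likelihood cache or (samples, curve).
    """
    if isinstance(cache_or_samples, _LikelihoodCache):
        cache = cache_or_samples
    else:
        cache = precompute_likelihood(cache_or_samples, curve, pmf.window)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = cache.scaled * pmf.p[None, :]
    totals = W.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DomainError("full conditional has zero mass for at least one date")
    cdf = np.cumsum(W / totals, axis=1)
    u = rng.random((cache.n, 1))
    idx = (cdf < u).sum(axis=1)
    return pmf.window.years[idx]


def _run_chain(
    variant: str,
    window: Window,
    priors: dict,
    cache: _LikelihoodCache,
    config: MCMCConfig,
    rng: np.random.Generator,
    save_latent: bool,
):
    names = [n for n in PARAM_NAMES[variant] if priors[n].is_free]
    fixed = {n: priors[n].params[0] for n in PARAM_NAMES[variant] if not priors[n].is_free}

    def logpost(params: dict) -> float:
        lp = sum(priors[n].logpdf(params[n]) for n in names)
        if not np.isfinite(lp):
            return -np.inf
        try:
            pmf = build_pmf(variant, window, params)
        except DomainError:
            return -np.inf
        return lp + marginal_loglik(cache, pmf)

    # initialise from the priors; retry until the posterior is finite
    current = None
    for _ in range(200):
        cand = dict(fixed)
        for n in names:
            cand[n] = priors[n].sample(rng)
        lp = logpost(cand)
        if np.isfinite(lp):
            current, cur_lp = cand, lp
            break
    if current is None:
        raise InitializationError(
            "no prior draw gave a finite posterior in 200 attempts; "
            "check priors, window and data"
        )

    scales = {n: (config.initial_scale or {}).get(n, max(abs(current[n]) * 0.1, priors[n].sd * 0.1, 1e-5))
              for n in names}
    accepted = {n: 0 for n in names}
    window_acc = {n: 0 for n in names}
    adapt_rounds = 0

    keep = [i for i in range(config.n_burnin, config.n_iterations)
            if (i - config.n_burnin) % config.thin == 0]
    keep_set = set(keep)
    out = {n: np.empty(len(keep)) for n in names}
    latent = np.empty((len(keep), cache.n), dtype=float) if save_latent else None
    k = 0

    for it in range(config.n_iterations):
        for n in names:
            prop = dict(current)
            prop[n] = current[n] + scales[n] * rng.standard_normal()
            prop_lp = logpost(prop)
            if np.log(rng.random()) < prop_lp - cur_lp:
                current, cur_lp = prop, prop_lp
                accepted[n] += 1
                window_acc[n] += 1
        if (it + 1) % config.adapt_interval == 0:
            adapt_rounds += 1
            gain = 1.0 / math.sqrt(adapt_rounds)
            for n in names:
                rate = window_acc[n] / config.adapt_interval
                scales[n] *= math.exp(gain * (rate - config.target_acceptance))
                window_acc[n] = 0
        if it in keep_set:
            for n in names:
                out[n][k] = current[n]
            if save_latent:
                pmf = build_pmf(variant, window, current)
                latent[k] = sample_latent_dates(pmf, cache, seed=rng)
            k += 1

    acc_rates = {n: accepted[n] / config.n_iterations for n in names}
    return out, acc_rates, latent, names


def fit_mcmc(
    samples: Sequence[C14Sample],
    variant: str,
    window: WindowLike,
    priors: dict,
    curve: CalCurve,
    config: MCMCConfig,
    save_latent: bool = False,
) -> PosteriorSamples:
    """Fit a growth model to radiocarbon determinations by MCMC.

    Parameters
    ----------
    samples
        Determinations, ideally pre-screened with
        :func:`~c14growth.caldate.window_filter`.
    variant
        One of ``exponential``, ``double_exponential``, ``exp_logistic``.
    window
        Analysis window [b, a]; its boundaries are fixed constants.
    priors
        Mapping of parameter name to :class:`PriorSpec`; every free
        parameter of the variant must be present (``fixed`` pins one).
    config
        Chains, iterations, burn-in, thinning, seed, adaptation.

    With an empty sample list the sampler targets the prior, which is the
    standard detailed-balance sanity check. Runs are bitwise reproducible
    for a given seed and config.
    """
    window = as_window(window)
    if variant not in PARAM_NAMES:
        raise ConfigError(f"unknown growth-model variant {variant!r}")
    missing = [n for n in PARAM_NAMES[variant] if n not in priors]
    if missing:
        raise ConfigError(f"missing prior(s) for parameter(s): {missing}")
    cache = precompute_likelihood(samples, curve, window)

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)
    chain_draws, chain_acc, chain_latent = [], [], []
    names = None
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        out, acc, latent, names = _run_chain(
            variant, window, priors, cache, config, rng, save_latent
        )
        chain_draws.append(out)
        chain_acc.append(acc)
        chain_latent.append(latent)

    draws = {n: np.stack([cd[n] for cd in chain_draws]) for n in names}
    acceptance = {n: [ca[n] for ca in chain_acc] for n in names}
    latent = np.stack(chain_latent) if save_latent else None
    return PosteriorSamples(
        variant=variant,
        window=window,
        draws=draws,
        acceptance=acceptance,
        config=config,
        latent=latent,
        param_names=tuple(names),
    )


def pointwise_loglik(
    posterior: PosteriorSamples,
    samples: Sequence[C14Sample],
    curve: CalCurve,
    n_draws: Optional[int] = None,
    seed=None,
) -> np.ndarray:
    """(S x J) matrix of per-date marginal log likelihoods over posterior draws.

    This is the observation-level predictive density used by WAIC: for
    each retained draw of the growth parameters, the latent date is summed
    out over the calendar grid. ``n_draws`` subsamples the posterior
    without replacement (all draws when None).
    """
    cache = precompute_likelihood(samples, curve, posterior.window)
    total = posterior.n_draws
    if n_draws is None or n_draws >= total:
        idx = np.arange(total)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.choice(total, size=n_draws, replace=False)
    out = np.empty((len(idx), cache.n))
    for s, i in enumerate(idx):
        pmf = build_pmf(posterior.variant, posterior.window, posterior.draw_params(int(i)))
        inner = cache.scaled @ pmf.p
        with np.errstate(divide="ignore"):
            out[s] = np.log(inner) + cache.rowmax
    return out
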