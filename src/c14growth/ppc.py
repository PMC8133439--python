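"""Posterior-predictive checks on summed probability distributions.

For each of ``n_sim`` iterations the generative chain is replayed with a
parameter combination drawn from the posterior: sample calendar dates
from the fitted growth model, back-calibrate each into a 14C age, attach
a lab error resampled from the observed errors, calibrate, and sum into a
normalised SPD. The pointwise 2.5%/97.5% quantiles across iterations form
a 95% simulation envelope against which the observed SPD is compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import PosteriorSamples, build_pmf
from .calcurve import CalCurve, grid_curve
from .caldate import SPDGrid
from .errors import ConfigError, GridError
from .growth import sample_calendar_dates

__all__ = ["PPCEnvelope", "CoverageReport", "posterior_predictive_spd", "envelope_coverage"]


@dataclass(frozen=True)
class PPCEnvelope:
    """Pointwise simulation envelope for an SPD.

    ``lo``/``hi`` are per-year quantile bounds over ``n_sim`` simulated
    normalised SPDs; ``observed`` is the observed SPD density (or None),
    ``mean`` the pointwise mean of the simulations.
    """

    grid: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    observed: Optional[np.ndarray]
    n_sim: int
    level: float
    mean: Optional[np.ndarray] = None

    def to_dataframe(self) -> pd.DataFrame:
        data = {"calbp": self.grid, "lo": self.lo, "hi": self.hi}
        if self.observed is not None:
            data["observed"] = self.observed
        return pd.DataFrame(data)


@dataclass(frozen=True)
class CoverageReport:
    """Fraction of years where the observed SPD sits inside the envelope,
    plus the out-of-envelope years split by sign of the deviation."""

    fraction: float
    years_above: np.ndarray
    years_below: np.ndarray


def posterior_predictive_spd(
    posterior: PosteriorSamples,
    n_dates: int,
    observed_errors: Sequence[float],
    curve: CalCurve,
    observed_spd: Optional[SPDGrid] = None,
    n_sim: int = 500,
    level: float = 0.95,
    seed=None,
    method: str = "uncalsample",
) -> PPCEnvelope:
    """Simulate an SPD ensemble from the posterior and form its envelope.

    Parameters
    ----------
    posterior
        Fitted growth-model draws; each simulation uses one randomly
        chosen parameter combination.
    n_dates
        Dates per simulated SPD; by convention the observed sample count.
    observed_errors
        Pool of observed lab errors, resampled with replacement.
    method
        ``uncalsample`` (default): the five-step recipe — calendar draws,
        back-calibration with measurement noise, calibration, summation.
        ``calsample``: best-effort variant that pushes calendar draws
        through the curve without a measurement-noise draw before
        calibrating (the smear is then curve+lab error only).

    Deterministic given ``seed``. The envelope is pointwise (per-year),
    not simultaneous.
    """
    if n_sim < 2:
        raise ConfigError("n_sim must be >= 2")
    if len(observed_errors) == 0:
        raise ConfigError("observed_errors must be non-empty")
    if posterior.n_draws == 0:
        raise ConfigError("posterior is empty")
    if method not in ("uncalsample", "calsample"):
        raise ConfigError(f"unknown ppc method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window = posterior.window
    g = grid_curve(curve, window.a, window.b)
    errors = np.asarray(observed_errors, dtype=float)
    total = posterior.n_draws
    sims = np.empty((n_sim, window.T + 1))
    years_desc = window.years.astype(float)
    mu = g.mu
    tau = g.tau
    log_sqrt_2pi = 0.5 * np.log(2 * np.pi)
    for s in range(n_sim):
        params = posterior.draw_params(int(rng.integers(total)))
        pmf = build_pmf(posterior.variant, window, params)
        theta = sample_calendar_dates(pmf, n_dates, rng)
        idx = (window.a - theta).astype(int)
        sig_lab = rng.choice(errors, size=n_dates, replace=True)
        sig_date = np.hypot(tau[idx], sig_lab)
        if method == "uncalsample":
            x = rng.normal(mu[idx], sig_date)
        else:  # calsample: no measurement-noise draw, smear only
            x = mu[idx]
        # vectorised calibration of all simulated dates over the window grid
        sig = np.hypot(sig_lab[:, None], tau[None, :])
        z = (x[:, None] - mu[None, :]) / sig
        L = -0.5 * z * z - np.log(sig) - log_sqrt_2pi
        L -= L.max(axis=1, keepdims=True)
        mass = np.exp(L)
        mass /= mass.sum(axis=1, keepdims=True)
        sims[s] = mass.mean(axis=0)  # normalised SPD
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(sims, alpha, axis=0)
    hi = np.quantile(sims, 1.0 - alpha, axis=0)
    observed = None
    if observed_spd is not None:
        if observed_spd.grid.shape != years_desc.shape or np.any(observed_spd.grid != years_desc):
            raise GridError("observed SPD grid does not match the posterior window")
        observed = observed_spd.density / observed_spd.density.sum()
    return PPCEnvelope(
        grid=years_desc,
        lo=lo,
        hi=hi,
        observed=observed,
        n_sim=n_sim,
        level=level,
        mean=sims.mean(axis=0),
    )


def envelope_coverage(envelope: PPCEnvelope, observed: Optional[np.ndarray] = None) -> CoverageReport:
    """Fraction of years with the observed SPD inside [lo, hi] (inclusive).

    ``observed`` overrides the envelope's stored observed density; the
    report also lists the years deviating above and below the envelope.
    """
    obs = observed if observed is not None else envelope.observed
    if obs is None:
        raise GridError("no observed SPD attached to the envelope")
    obs = np.asarray(obs, dtype=float)
    if obs.shape != envelope.grid.shape:
        raise GridError("observed density length does not match the envelope grid")
    above = obs > envelope.hi
    below = obs < envelope.lo
    inside = ~(above | below)
    return CoverageReport(
        fraction=float(inside.mean()),
        years_above=envelope.grid[above],
        years_below=envelope.grid[below],
    )
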