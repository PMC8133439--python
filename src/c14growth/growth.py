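"""Bounded demographic growth models as probability masses over calendar years.

A *bounded growth model* on a window of calendar years [b, a] (a older,
b younger, both cal BP) is a generalised Bernoulli (categorical)
distribution: the probability of drawing a calendar date ``t`` is ``p_t``,
with ``p_t = 0`` outside the window. Time is discrete (one-year steps),
indexed ``i = 0`` at ``t = a`` through ``i = T = a - b`` at ``t = b``;
a positive growth rate therefore means growth toward the present.

Any population trajectory ``N_t > 0`` induces such a model via
``p = N / sum(N)``; closed-form builders are provided for the exponential,
double-exponential (changepoint) and exponential-logistic families. All
builders work in log space and normalise with log-sum-exp, so rates up to
~0.01 on windows of 10,000 years do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .errors import DomainError

__all__ = [
    "Window",
    "GrowthPMF",
    "pmf_exponential",
    "pmf_double_exponential",
    "pmf_exp_logistic",
    "pmf_from_trajectory",
    "sample_calendar_dates",
]


@dataclass(frozen=True)
class Window:
    """Closed analysis window [b, a] in integer cal BP; a > b."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if int(self.a) != self.a or int(self.b) != self.b:
            raise DomainError("window boundaries must be integers")
        object.__setattr__(self, "a", int(self.a))
        object.__setattr__(self, "b", int(self.b))
        if self.a <= self.b:
            raise DomainError(f"window requires a > b, got a={self.a}, b={self.b}")

    @property
    def T(self) -> int:
        return self.a - self.b

    @property
    def years(self) -> np.ndarray:
        """Calendar years a, a-1, ..., b (oldest first; index i = a - t)."""
        return np.arange(self.a, self.b - 1, -1)


WindowLike = Union[Window, tuple, Sequence]


def as_window(window: WindowLike) -> Window:
    """Coerce a Window or an (older, younger) / unordered pair to Window."""
    if isinstance(window, Window):
        return window
    a, b = window
    if a < b:
        a, b = b, a
    return Window(int(a), int(b))


@dataclass(frozen=True)
class GrowthPMF:
    """Probability mass over the calendar years of a window.

    ``p[i]`` is the probability of year ``t = a - i``; length T+1, sums
    to 1 (enforced to 1e-9), implicitly zero outside [b, a].
    """

    window: Window
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != self.window.T + 1:
            raise DomainError("pmf length must equal window.T + 1")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise DomainError("pmf values must be finite and non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise DomainError(f"pmf must sum to 1 (got {p.sum():.12f})")
        object.__setattr__(self, "p", p)

    @property
    def years(self) -> np.ndarray:
        return self.window.years

    def prob_at(self, t) -> np.ndarray:
        """p_t for calendar year(s) t; zero outside the window."""
        t = np.asarray(t)
        i = self.window.a - t
        inside = (i >= 0) & (i <= self.window.T)
        out = np.zeros(t.shape, dtype=float)
        out[inside] = self.p[i[inside].astype(int)]
        return out


def _normalise(logp: np.ndarray, window: Window) -> GrowthPMF:
    # max-shifted exponentiation == log-sum-exp normalisation, minus overhead
    p = np.exp(logp - logp.max())
    return GrowthPMF(window, p / p.sum())


def pmf_exponential(window: WindowLike, r: float) -> GrowthPMF:
    """Bounded exponential growth: p_{t=a-i} proportional to (1+r)^i.

    r = 0 gives the uniform (phase-model) distribution; r > -1 required.
    """
    window = as_window(window)
    if r <= -1:
        raise DomainError("exponential rate must satisfy r > -1")
    i = np.arange(window.T + 1, dtype=float)
    return _normalise(i * np.log1p(r), window)


def pmf_double_exponential(window: WindowLike, r1: float, r2: float, c: float) -> GrowthPMF:
    """Two-phase exponential growth with a changepoint at year ``c``.

    The annual growth rate in year ``t`` is ``r1`` for ``t > c`` and
    ``r2`` for ``t <= c``; the trajectory steps ``N_{t-1} = N_t (1 + r(t))``
    so it is continuous through the handover and, for r1 > 0 > r2, peaks
    exactly at the changepoint. ``c`` need not be an integer (the
    comparison ``t > c`` is applied to integer years directly), which
    keeps the likelihood continuous in ``c`` during MCMC.
    """
    window = as_window(window)
    if not (window.b < c < window.a):
        raise DomainError(f"changepoint c={c} must lie strictly inside ({window.b}, {window.a})")
    if r1 <= -1 or r2 <= -1:
        raise DomainError("growth rates must satisfy r > -1")
    years = window.years.astype(float)
    src = years[:-1]  # year whose rate drives the step to the next (younger) year
    steps = np.where(src > c, np.log1p(r1), np.log1p(r2))
    logp = np.concatenate([[0.0], np.cumsum(steps)])
    return _normalise(logp, window)


def pmf_exp_logistic(
    window: WindowLike,
    r1: float,
    r2: float,
    c: float,
    k: float,
    changepoint_relative: bool = False,
) -> GrowthPMF:
    """Exponential-then-logistic growth with a changepoint at year ``c``.

    For ``t > c`` the trajectory is exponential, ``k (1+r1)^i``; for
    ``t <= c`` it follows a logistic approach to carrying capacity 1 with
    intrinsic rate ``r2``. ``k`` in (0, 1) is the population at ``t = a``
    as a proportion of the carrying capacity.

    By default the logistic exponent uses the global index ``i = a - t``.
    With ``changepoint_relative=True`` the exponent is measured from the
    changepoint (``i - (a - c)``), which makes the trajectory continuous
    at ``t = c``; the default matches the model family as usually printed.

    Raises
    ------
    DomainError
        If ``k (1+r1)^(a-c) >= 1`` (the logistic fraction is ill-defined).
    """
    window = as_window(window)
    if not (window.b < c < window.a):
        raise DomainError(f"changepoint c={c} must lie strictly inside ({window.b}, {window.a})")
    if not (0 < k < 1):
        raise DomainError("k must lie in (0, 1)")
    if r1 <= -1:
        raise DomainError("r1 must satisfy r > -1")
    i = np.arange(window.T + 1, dtype=float)
    t = window.a - i
    logK = np.log(k) + (window.a - c) * np.log1p(r1)  # population proportion at t = c
    if logK >= 0:
        raise DomainError("k (1+r1)^(a-c) must be < 1 for the logistic phase")
    logA = np.log1p(-np.exp(logK)) - logK  # (1-K)/K
    expo = -r2 * (i - (window.a - c)) if changepoint_relative else -r2 * i
    log_exp_part = np.log(k) + i * np.log1p(r1)
    log_logi_part = -np.logaddexp(0.0, logA + expo)
    logp = np.where(t > c, log_exp_part, log_logi_part)
    return _normalise(logp, window)


def pmf_from_trajectory(window: WindowLike, N: Sequence[float]) -> GrowthPMF:
    """Turn any positive population trajectory (oldest first) into a PMF."""
    window = as_window(window)
    N = np.asarray(N, dtype=float)
    if len(N) != window.T + 1:
        raise DomainError("trajectory length must equal window.T + 1")
    if np.any(N <= 0) or not np.all(np.isfinite(N)):
        raise DomainError("trajectory values must be finite and positive")
    return GrowthPMF(window, N / N.sum())


def sample_calendar_dates(pmf: GrowthPMF, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` iid calendar years (cal BP) from a growth PMF."""
    if n < 0:
        raise DomainError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = pmf.p / pmf.p.sum()  # guard against 1e-16 normalisation slack
    return rng.choice(pmf.years, size=int(n), p=p)
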