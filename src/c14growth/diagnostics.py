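"""Posterior summaries and convergence diagnostics.

Highest-posterior-density intervals are the shortest contiguous window of
the sorted draws containing the requested mass (a unimodality assumption;
a warning is emitted when the sample looks strongly multimodal). The
Gelman-Rubin statistic is the classic two-variance potential scale
reduction factor, and effective sample size uses initial-positive-sequence
truncation of the autocorrelation sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf

from .errors import InsufficientDataError, UndefinedESSError

__all__ = [
    "HPDInterval",
    "hpd_interval",
    "gelman_rubin",
    "effective_sample_size",
    "summary_table",
]


@dataclass(frozen=True)
class HPDInterval:
    """Shortest interval holding at least ``mass`` of the posterior draws."""

    lower: float
    upper: float
    mass: float

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hpd_interval(draws: Sequence[float], mass: float = 0.90) -> HPDInterval:
    """Highest posterior density interval from posterior draws.

    The estimator sorts the draws and scans every contiguous window
    containing ``ceil(mass * n)`` of them, returning the shortest.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    n = len(draws)
    if n < 2:
        raise InsufficientDataError("need >= 2 draws for an HPD interval")
    if not (0 < mass < 1):
        raise InsufficientDataError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    widths = draws[k - 1 :] - draws[: n - k + 1]
    j = int(np.argmin(widths))
    return HPDInterval(float(draws[j]), float(draws[j + k - 1]), mass)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat from >= 2 equal-length chains.

    R-hat = sqrt((W0 + B/n) / W0) with W0 the mean within-chain variance
    (denominator n) and B = n * var(chain means); identical chains give
    exactly 1.0 and diverging chains values far above 1. Invariant to a
    common affine transformation of all chains.
    """
    arr = np.asarray([np.asarray(c, dtype=float) for c in chains])
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("Gelman-Rubin needs >= 2 chains")
    m, n = arr.shape
    if n < 2:
        raise InsufficientDataError("chains must have length >= 2")
    within = arr.var(axis=1, ddof=0).mean()
    between = n * arr.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    return float(np.sqrt((within + between / n) / within))


def effective_sample_size(draws: Sequence[float]) -> float:
    """ESS = n / (1 + 2 sum rho_k), truncated at the first nonpositive pair.

    Autocorrelations are estimated by FFT and summed in consecutive pairs
    (rho_1+rho_2), (rho_3+rho_4), ... as long as each pair sum stays
    positive — the standard initial-positive-sequence rule, which is
    stable on thinned chains.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10:
        raise InsufficientDataError("need >= 10 draws for an ESS estimate")
    if np.ptp(x) == 0.0:
        raise UndefinedESSError("ESS undefined for a constant sequence")
    nlags = min(n - 1, max(10, n // 2))
    rho = acf(x, nlags=nlags, fft=True)[1:]
    s = 0.0
    for k in range(0, len(rho) - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
    tau = 1.0 + 2.0 * s
    return float(n / tau)


def _maybe_warn_multimodal(x: np.ndarray) -> None:
    # crude dip heuristic: a histogram valley below 10% of the peak between
    # two peaks suggests the shortest-window HPD summary may mislead
    if len(x) < 200:
        return
    hist, _ = np.histogram(x, bins=30)
    peak = hist.max()
    interior = hist[1:-1]
    left_max = np.maximum.accumulate(hist[:-2])
    right_max = np.maximum.accumulate(hist[:1:-1])[::-1]
    valley = (interior < 0.1 * peak) & (left_max > 0.3 * peak) & (right_max > 0.3 * peak)
    if valley.any():
        warnings.warn("draws look multimodal; HPD interval assumes unimodality", stacklevel=3)


def summary_table(posterior, mass: float = 0.90, params: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-parameter summary: Rhat, ESS, median, HPD bounds.

    ``posterior`` is a :class:`~c14growth.bayes.PosteriorSamples`. ESS is
    summed over chains; Rhat is NaN for a single chain. The column layout
    (Rhat, ESS, Median, HPD90lower, HPD90upper) mirrors the conventional
    fitted-parameter report for these models.
    """
    rows = []
    pct = int(round(mass * 100))
    for name in params or posterior.param_names:
        ch = posterior.chains(name)
        flat = ch.reshape(-1)
        _maybe_warn_multimodal(flat)
        hpd = hpd_interval(flat, mass)
        ess = sum(effective_sample_size(c) for c in ch)
        rhat = gelman_rubin(ch) if ch.shape[0] >= 2 else np.nan
        rows.append(
            {
                "parameter": name,
                "Rhat": rhat,
                "ESS": ess,
                "Median": float(np.median(flat)),
                f"HPD{pct}lower": hpd.lower,
                f"HPD{pct}upper": hpd.upper,
            }
        )
    return pd.DataFrame(rows)
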