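"""WAIC model comparison.

The widely applicable information criterion is computed from a matrix of
pointwise posterior log likelihoods (S draws x J observations):

    lppd   = sum_j log( mean_s exp(ll_sj) )
    p_waic = sum_j var_s(ll_sj)
    WAIC   = -2 (lppd - p_waic)

Lower is better. Model weights follow the Akaike-weight convention
``w_i = exp(-Delta_i / 2) / sum exp(-Delta / 2)`` on the WAIC differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DomainError

__all__ = ["WAICResult", "waic", "compare"]


@dataclass
class WAICResult:
    """WAIC and its components for one model.

    ``delta`` and ``weight`` are filled in by :func:`compare`.
    """

    waic: float
    lppd: float = np.nan
    p_waic: float = np.nan
    name: Optional[str] = None
    delta: float = field(default=np.nan)
    weight: float = field(default=np.nan)


def waic(loglik: np.ndarray, name: Optional[str] = None) -> WAICResult:
    """Compute WAIC from an (S x J) pointwise log-likelihood matrix.

    Rows are posterior draws, columns observations; needs S >= 2 draws and
    finite entries. The log of the posterior-mean likelihood is evaluated
    with log-sum-exp; the penalty uses the sample variance (ddof=1).
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise DomainError("loglik must be a 2-d (draws x observations) matrix")
    S, J = ll.shape
    if S < 2 or J < 1:
        raise DomainError("need >= 2 draws and >= 1 observation")
    if not np.all(np.isfinite(ll)):
        raise DomainError("loglik entries must be finite")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return WAICResult(waic=-2.0 * (lppd - p_waic), lppd=lppd, p_waic=p_waic, name=name)


def compare(results: Sequence[WAICResult]) -> pd.DataFrame:
    """Rank models by WAIC: Delta-WAIC from the best and Akaike-style weights.

    Mutates each result's ``delta``/``weight`` and returns a table sorted
    ascending by WAIC with columns model, WAIC, dWAIC, weight.
    """
    if len(results) == 0:
        raise DomainError("need at least one model")
    waics = np.array([r.waic for r in results], dtype=float)
    deltas = waics - waics.min()
    w = np.exp(-deltas / 2.0)
    w = w / w.sum()
    for r, d, wi in zip(results, deltas, w):
        r.delta = float(d)
        r.weight = float(wi)
    df = pd.DataFrame(
        {
            "model": [r.name or f"model{i}" for i, r in enumerate(results, 1)],
            "WAIC": waics,
            "dWAIC": deltas,
            "weight": w,
        }
    )
    return df.sort_values("WAIC", kind="stable").reset_index(drop=True)
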