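"""Calibration of radiocarbon determinations and summed probability distributions.

Calibrating a determination ``x +/- sigma_lab`` against a curve
``mu(t) +/- tau(t)`` yields a probability mass over calendar years
proportional to ``Normal(x; mu(t), sqrt(sigma_lab^2 + tau(t)^2))``,
normalised over the analysis grid. Back-calibration (uncalibration) runs
the measurement model forward: a simulated 14C age for a known calendar
year is a single Normal draw with the same combined standard deviation
(the curve-draw-then-counting-noise two-stage scheme collapses to one
Gaussian because the two errors are independent).

The summed probability distribution (SPD) is the elementwise sum of many
calibrated dates; it is the field's conventional population-size proxy and
here serves as the observable for posterior-predictive checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .calcurve import CalCurve, grid_curve
from .errors import DegenerateSupportError, DomainError, GridError
from .growth import WindowLike, as_window

__all__ = [
    "C14Sample",
    "CalibratedDate",
    "SPDGrid",
    "read_dates",
    "write_dates",
    "combined_sigma",
    "calibrate_date",
    "uncalibrate",
    "spd",
    "window_filter",
]

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


@dataclass(frozen=True)
class C14Sample:
    """A radiocarbon determination: lab code, 14C age BP, 1-sigma lab error."""

    labcode: str
    x: float
    sigma_lab: float
    site: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.x):
            raise DomainError(f"{self.labcode}: 14C age must be finite")
        if not (self.sigma_lab > 0 and np.isfinite(self.sigma_lab)):
            raise DomainError(f"{self.labcode}: sigma_lab must be positive")


@dataclass(frozen=True)
class CalibratedDate:
    """Probability mass over a descending calendar-year grid; sums to 1."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.shape != mass.shape or grid.ndim != 1:
            raise GridError("grid and mass must be 1-d arrays of equal length")
        if np.any(mass < 0):
            raise DomainError("calibrated mass must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise DomainError(f"calibrated mass must sum to 1 (got {mass.sum():.12f})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", mass)

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.mass))])

    def mass_between(self, lo: float, hi: float) -> float:
        """Total mass on grid years in the closed interval [lo, hi]."""
        sel = (self.grid >= lo) & (self.grid <= hi)
        return float(self.mass[sel].sum())


@dataclass(frozen=True)
class SPDGrid:
    """Summed probability distribution over a calendar grid.

    ``density`` totals ``n`` (unnormalised) or 1 (normalised).
    """

    grid: np.ndarray
    density: np.ndarray
    n: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        if grid.shape != density.shape:
            raise GridError("grid and density must have equal length")
        if np.any(density < 0):
            raise DomainError("SPD density must be non-negative")
        total = density.sum()
        if not (abs(total - self.n) <= 1e-9 * max(1, self.n) or abs(total - 1.0) <= 1e-9):
            raise DomainError(f"SPD must total n or 1, got {total:.12f}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)


def read_dates(source: Union[str, Path, IO[str]]) -> list[C14Sample]:
    """Read determinations from CSV with columns labcode, c14age, error[, site]."""
    df = pd.read_csv(source)
    required = {"labcode", "c14age", "error"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"dates CSV missing required columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        site = getattr(row, "site", None)
        if site is not None and (isinstance(site, float) and np.isnan(site)):
            site = None
        out.append(
            C14Sample(
                labcode=str(row.labcode),
                x=float(row.c14age),
                sigma_lab=float(row.error),
                site=None if site is None else str(site),
            )
        )
    return out


def write_dates(samples: Sequence[C14Sample], dest: Union[str, Path, IO[str]]) -> None:
    """Write determinations to the CSV dialect read by :func:`read_dates`."""
    pd.DataFrame(
        {
            "labcode": [s.labcode for s in samples],
            "c14age": [s.x for s in samples],
            "error": [s.sigma_lab for s in samples],
            "site": [s.site for s in samples],
        }
    ).to_csv(dest, index=False)


def combined_sigma(sample: C14Sample, curve: CalCurve, t: float) -> float:
    """sqrt(sigma_lab^2 + tau(t)^2): lab and curve errors in quadrature."""
    curve.require_on_grid(t)
    tau = float(curve.tau_at(t))
    return float(np.hypot(sample.sigma_lab, tau))


def _loglik_grid(x: float, sigma_lab: float, curve: CalCurve) -> np.ndarray:
    """log Normal(x; mu(t), combined sigma) on the curve's own grid."""
    sig = np.hypot(sigma_lab, curve.tau)
    z = (x - curve.mu) / sig
    return -0.5 * z * z - np.log(sig) - _LOG_SQRT_2PI


def calibrate_date(sample: C14Sample, curve: CalCurve, window: WindowLike | None = None) -> CalibratedDate:
    """Calibrate one determination to a probability mass on a yearly grid.

    When ``window`` is given the curve is first gridded to it and the mass
    normalised within it (the analysis-window convention used by the
    likelihood); otherwise the curve must already be yearly-gridded and
    normalisation is over its full extent.
    """
    if window is not None:
        w = as_window(window)
        curve = grid_curve(curve, w.a, w.b)
    elif not curve.is_yearly:
        raise GridError("curve must be gridded to 1-year spacing (pass a window or grid_curve first)")
    logf = _loglik_grid(sample.x, sample.sigma_lab, curve)
    norm = logsumexp(logf)
    # every density representable as a double underflows to 0 below ~exp(-745)
    if not np.isfinite(norm) or logf.max() < -745.0:
        raise DegenerateSupportError(
            f"{sample.labcode}: calibrated mass underflowed everywhere on the grid"
        )
    return CalibratedDate(curve.calbp.copy(), np.exp(logf - norm))


def uncalibrate(t, curve: CalCurve, sigma_lab: float, seed=None):
    """Simulate 14C age(s) for known calendar year(s) ``t`` (back-calibration).

    Draws ``X ~ Normal(mu(t), sqrt(tau(t)^2 + sigma_lab^2))``; scalar in,
    scalar out. Deterministic given a seed or Generator.
    """
    curve.require_on_grid(t)
    if sigma_lab < 0:
        raise DomainError("sigma_lab must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_arr = np.asarray(t, dtype=float)
    mu = curve.mu_at(t_arr)
    sig = np.hypot(curve.tau_at(t_arr), sigma_lab)
    draw = rng.normal(mu, sig)
    return float(draw) if np.isscalar(t) or t_arr.ndim == 0 else draw


def spd(dates: Sequence[CalibratedDate], normalize: bool = False) -> SPDGrid:
    """Sum calibrated dates sharing one grid into an SPD."""
    if len(dates) == 0:
        raise DomainError("need at least one calibrated date")
    grid = dates[0].grid
    for d in dates[1:]:
        if d.grid.shape != grid.shape or np.any(d.grid != grid):
            raise GridError("all calibrated dates must share one calendar grid")
    density = np.sum([d.mass for d in dates], axis=0)
    n = len(dates)
    if normalize:
        density = density / n
    return SPDGrid(grid.copy(), density, n)


def window_filter(
    samples: Sequence[C14Sample],
    curve: CalCurve,
    window: WindowLike,
    threshold: float = 0.5,
) -> tuple[list[C14Sample], pd.DataFrame]:
    """Keep samples whose calibrated mass inside the window is >= threshold.

    Calibration here is over the FULL curve span (gridded yearly), so the
    in-window mass is the cumulative calibrated probability between the
    window boundaries; a sample is retained when that mass is >= the
    threshold (inclusive — only strictly-below-threshold dates drop out).
    Returns the kept subset and a per-sample report
    (labcode, in_window_mass, kept).
    """
    if not (0 < threshold <= 1):
        raise DomainError("threshold must lie in (0, 1]")
    w = as_window(window)
    lo, hi = curve.span
    full = curve if curve.is_yearly else grid_curve(curve, int(np.floor(hi)), int(np.ceil(lo)))
    kept: list[C14Sample] = []
    rows = []
    for s in samples:
        try:
            cal = calibrate_date(s, full)
            mass = cal.mass_between(w.b, w.a)
        except DegenerateSupportError:
            mass = 0.0
        keep = mass >= threshold
        if keep:
            kept.append(s)
        rows.append({"labcode": s.labcode, "in_window_mass": mass, "kept": keep})
    return kept, pd.DataFrame(rows)
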