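"""Radiocarbon calibration curves.

A calibration curve maps a calendar year ``t`` (cal BP, where 0 BP = 1950 CE
and larger values are older; a year in BCE is ``BP - 1950 + 1``, so
2664 BP corresponds to 715 BCE) to an expected conventional radiocarbon age
``mu(t)`` with a one-sigma curve uncertainty ``tau(t)``, both in 14C years.
Published curves such as IntCal20 are distributed as comma-separated
``.14c`` files with a ``#`` comment header and columns CAL BP, 14C age,
error (extra columns are ignored).

Curves are stored at their published knots and interpolated to a one-year
grid before use in the discrete-time likelihood; interpolation of both
``mu`` and ``tau`` is linear, the standard choice of calibration software.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .errors import DomainError, InsufficientDataError, ParseError

__all__ = [
    "CalCurve",
    "read_calcurve",
    "write_calcurve",
    "grid_curve",
    "synth_curve",
    "load_fixture_curve",
]

_FIXTURE_PATH = Path(__file__).parent / "data" / "synthetic_wiggle.14c"


@dataclass(frozen=True)
class CalCurve:
    """A calibration curve sampled at calendar-year knots, oldest first.

    Parameters
    ----------
    calbp
        Calendar years BP; unique, stored sorted descending (oldest first).
    mu
        Expected 14C age BP at each knot.
    tau
        One-sigma curve error in 14C years at each knot; non-negative.
    """

    calbp: np.ndarray
    mu: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        calbp = np.asarray(self.calbp, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if not (calbp.ndim == mu.ndim == tau.ndim == 1):
            raise DomainError("calbp, mu and tau must be one-dimensional")
        if not (len(calbp) == len(mu) == len(tau)):
            raise DomainError("calbp, mu and tau must have equal length")
        if len(calbp) < 2:
            raise InsufficientDataError("a calibration curve needs >= 2 knots")
        if np.unique(calbp).size != calbp.size:
            raise DomainError("calbp values must be unique")
        if np.any(tau < 0):
            raise DomainError("tau must be non-negative everywhere")
        order = np.argsort(calbp)[::-1]  # store oldest first
        object.__setattr__(self, "calbp", calbp[order])
        object.__setattr__(self, "mu", mu[order])
        object.__setattr__(self, "tau", tau[order])

    def __len__(self) -> int:
        return len(self.calbp)

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) calendar year covered."""
        return float(self.calbp[-1]), float(self.calbp[0])

    @property
    def is_yearly(self) -> bool:
        """True when knots are spaced exactly one calendar year apart."""
        return bool(np.all(np.diff(self.calbp) == -1.0))

    def mu_at(self, t):
        """Linearly interpolated mu(t); t may be scalar or array."""
        return np.interp(t, self.calbp[::-1], self.mu[::-1])

    def tau_at(self, t):
        """Linearly interpolated tau(t); t may be scalar or array."""
        return np.interp(t, self.calbp[::-1], self.tau[::-1])

    def require_on_grid(self, t) -> None:
        t = np.asarray(t, dtype=float)
        lo, hi = self.span
        if np.any(t < lo) or np.any(t > hi):
            raise DomainError(
                f"calendar year(s) outside curve span [{lo}, {hi}]"
            )
        if not np.all(np.isin(t, self.calbp)):
            raise DomainError("calendar year(s) not on the curve grid")


def read_calcurve(source: Union[str, Path, IO[str]]) -> CalCurve:
    """Read a curve from a ``.14c``-dialect file or text stream.

    Lines starting with ``#`` are comments; data lines are comma-separated
    with at least three numeric columns (CAL BP, 14C age, error); any
    further columns (e.g. Delta-14C) are ignored.

    Raises
    ------
    ParseError
        On a malformed numeric field, naming the offending line.
    InsufficientDataError
        When fewer than two data rows are present.
    """
    if hasattr(source, "read"):
        lines: Iterable[str] = source  # type: ignore[assignment]
    else:
        lines = Path(source).read_text().splitlines()
    calbp, mu, tau = [], [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: expected >= 3 comma-separated fields")
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed numeric field ({exc})") from exc
        if not all(math.isfinite(v) for v in vals):
            raise ParseError(f"line {lineno}: non-finite value")
        calbp.append(vals[0])
        mu.append(vals[1])
        tau.append(vals[2])
    if len(calbp) < 2:
        raise InsufficientDataError("fewer than 2 data rows in calibration curve")
    return CalCurve(np.array(calbp), np.array(mu), np.array(tau))


def write_calcurve(curve: CalCurve, dest: Union[str, Path, IO[str]], header: str = "CAL BP, 14C age, error") -> None:
    """Write a curve in the ``.14c`` dialect; round-trips exactly."""
    buf = io.StringIO()
    buf.write(f"# {header}\n")
    for t, m, s in zip(curve.calbp, curve.mu, curve.tau):
        buf.write(f"{float(t)!r},{float(m)!r},{float(s)!r}\n")
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)  # type: ignore[union-attr]
    else:
        Path(dest).write_text(text)


def grid_curve(curve: CalCurve, a: float, b: float) -> CalCurve:
    """Interpolate a curve to the one-year grid ``a, a-1, ..., b``.

    ``a`` is the older boundary, ``b`` the younger; both must lie inside
    the curve span. Knot values are preserved at knot years.
    """
    if a <= b:
        raise DomainError(f"window requires a > b, got a={a}, b={b}")
    lo, hi = curve.span
    if a > hi or b < lo:
        raise DomainError(f"window [{b}, {a}] outside curve span [{lo}, {hi}]")
    t = np.arange(a, b - 1, -1, dtype=float)
    return CalCurve(t, curve.mu_at(t), curve.tau_at(t))


def synth_curve(
    kind: str,
    span: tuple[float, float],
    tau0: float = 20.0,
    params: dict | None = None,
    seed: int | None = None,
) -> CalCurve:
    """Construct a synthetic calibration curve on a yearly grid.

    Useful for tests and simulation studies that should not depend on a
    downloaded curve file. ``span`` is any (end, end) pair of calendar
    years; the curve covers the closed interval between them.

    Kinds
    -----
    ``identity``
        mu(t) = t — makes calibration analytically a discretised Normal.
    ``linear``
        mu(t) = alpha + beta * t (params ``alpha``, ``beta``).
    ``plateau``
        identity outside a sub-interval (params ``region=(lo, hi)``),
        constant ``level`` inside — mimics a calibration plateau.
    ``steep``
        slope ``slope`` (> 1, default 3) inside ``region``, slope 1
        outside, continuous — mimics a steep stretch of the curve.
    ``wiggle``
        identity plus a smooth sinusoid (params ``amplitude``, ``period``);
        a seed randomises the phase, otherwise phase 0.

    tau(t) = tau0 everywhere.
    """
    if tau0 < 0:
        raise DomainError("tau0 must be >= 0")
    lo, hi = sorted(float(v) for v in span)
    if hi <= lo:
        raise DomainError("span must have positive length")
    params = dict(params or {})
    t = np.arange(hi, lo - 1, -1, dtype=float)
    if kind == "identity":
        mu = t.copy()
    elif kind == "linear":
        alpha = float(params.get("alpha", 0.0))
        beta = float(params.get("beta", 1.0))
        mu = alpha + beta * t
    elif kind == "plateau":
        r_lo, r_hi = params.get("region", (lo + (hi - lo) / 3, hi - (hi - lo) / 3))
        level = float(params.get("level", (r_lo + r_hi) / 2))
        mu = t.copy()
        inside = (t >= r_lo) & (t <= r_hi)
        mu[inside] = level
    elif kind == "steep":
        r_lo, r_hi = params.get("region", (lo + (hi - lo) / 3, hi - (hi - lo) / 3))
        slope = float(params.get("slope", 3.0))
        if slope <= 1.0:
            raise DomainError("steep curve requires slope > 1")
        # integrate dmu/dt from the young end so the curve stays continuous
        t_asc = t[::-1]
        dmu = np.where((t_asc[:-1] >= r_lo) & (t_asc[:-1] < r_hi), slope, 1.0)
        mu_asc = lo + np.concatenate([[0.0], np.cumsum(dmu)])
        mu = mu_asc[::-1].copy()
    elif kind == "wiggle":
        amplitude = float(params.get("amplitude", 25.0))
        period = float(params.get("period", 500.0))
        phase = 0.0
        if seed is not None:
            phase = float(np.random.default_rng(seed).uniform(0, 2 * np.pi))
        mu = t + amplitude * np.sin(2 * np.pi * t / period + phase)
    else:
        from .errors import ConfigError

        raise ConfigError(f"unknown synthetic curve kind: {kind!r}")
    return CalCurve(t, mu, np.full_like(t, float(tau0)))


def load_fixture_curve() -> CalCurve:
    """Load the vendored synthetic wiggle curve shipped with the package."""
    return read_calcurve(_FIXTURE_PATH)
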