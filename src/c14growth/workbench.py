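"""Simulation experiments and the case-study pipeline.

An :class:`ExperimentDesign` bundles everything needed for a seeded
parameter-recovery experiment: the generating growth model and its true
parameters, the analysis window, sample size, lab error, replicate count,
fitting priors and MCMC settings. :func:`run_experiment` replays the full
generative chain per replicate — sample calendar dates, back-calibrate
with the design's lab error, then fit by MCMC and score whether each true
parameter falls inside its 90% HPD interval.

:func:`case_study_pipeline` chains the standard empirical workflow:
data-hygiene filters (missing age or lab code, lab error above 100 14C
years, under-half calibrated mass inside the analysis window), fits of the
exponential (m1), double-exponential (m2) and exponential-logistic (m3)
models under weakly informative priors, a convergence/summary table, WAIC
comparison and posterior-predictive SPD envelopes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .bayes import (
    MCMCConfig,
    PriorSpec,
    PARAM_NAMES,
    build_pmf,
    fit_mcmc,
    pointwise_loglik,
)
from .calcurve import CalCurve
from .caldate import C14Sample, calibrate_date, spd, window_filter
from .diagnostics import hpd_interval, summary_table
from .errors import ConfigError, DomainError, InsufficientDataError
from .growth import Window, as_window, sample_calendar_dates
from .modelcomp import compare, waic
from .ppc import posterior_predictive_spd
from . import caldate as _caldate

__all__ = [
    "ExperimentDesign",
    "RecoveryReport",
    "run_experiment",
    "simulate_dates",
    "CaseStudyResult",
    "case_study_pipeline",
    "default_case_study_priors",
    "table1_designs",
    "manifest",
]

#: BP -> BCE conversion: 0 BP = 1950 CE, so BCE = BP - 1950 + 1.
def bp_to_bce(bp: float) -> float:
    return bp - 1950 + 1


# ---------------------------------------------------------------------------
# Experiment designs


@dataclass(frozen=True)
class ExperimentDesign:
    """One parameter setting of a seeded recovery experiment."""

    name: str
    variant: str
    true_params: dict
    window: Window
    n_dates: int
    priors: dict
    mcmc: MCMCConfig
    lab_error: float = 20.0
    n_replicates: int = 20

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.variant not in PARAM_NAMES:
            raise ConfigError(f"unknown growth-model variant {self.variant!r}")
        missing = [n for n in PARAM_NAMES[self.variant] if n not in self.priors]
        if missing:
            raise ConfigError(f"design {self.name}: missing prior(s) {missing}")
        # validate the true parameters by building the PMF once
        try:
            build_pmf(self.variant, self.window, self.true_params)
        except (DomainError, KeyError) as exc:
            raise ConfigError(f"design {self.name}: infeasible true parameters ({exc})") from exc

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variant": self.variant,
            "true_params": dict(self.true_params),
            "window": {"a": self.window.a, "b": self.window.b},
            "n_dates": self.n_dates,
            "lab_error": self.lab_error,
            "n_replicates": self.n_replicates,
            "priors": {k: {"dist": v.dist, "params": list(v.params)} for k, v in self.priors.items()},
            "mcmc": {k: v for k, v in dataclasses.asdict(self.mcmc).items() if v is not None},
        }

    @staticmethod
    def from_dict(d: dict) -> "ExperimentDesign":
        priors = {k: PriorSpec(v["dist"], tuple(v["params"])) for k, v in d["priors"].items()}
        return ExperimentDesign(
            name=d["name"],
            variant=d["variant"],
            true_params=dict(d["true_params"]),
            window=Window(d["window"]["a"], d["window"]["b"]),
            n_dates=int(d["n_dates"]),
            lab_error=float(d.get("lab_error", 20.0)),
            n_replicates=int(d.get("n_replicates", 20)),
            priors=priors,
            mcmc=MCMCConfig(**d.get("mcmc", {})),
        )

    def to_yaml(self, dest: Union[str, Path, IO[str]]) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text)

    @staticmethod
    def from_yaml(source: Union[str, Path, IO[str]]) -> "ExperimentDesign":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())  # type: ignore[union-attr]
        else:
            d = yaml.safe_load(Path(source).read_text())
        return ExperimentDesign.from_dict(d)


def _exp1_prior() -> dict:
    return {"r": PriorSpec.exponential(500.0)}


def _double_exp_priors(window: Window) -> dict:
    return {
        "r1": PriorSpec.normal(0.0, 0.1),
        "r2": PriorSpec.normal(0.0, 0.1),
        "c": PriorSpec.uniform(window.b + 1, window.a - 1),
    }


def table1_designs(mcmc: Optional[MCMCConfig] = None) -> dict:
    """The four standard simulation experiments as ready-made designs.

    Experiment 1: exponential, r in {0.001, 0.003, 0.005}, window
    6000-4000, n=500. Experiment 2: exponential r=0.003 on a steep
    (7000-6400) and a plateau (2800-2200) stretch of the curve, n=300.
    Experiment 3a: r=0.005 at n in {250, 100, 50}; 3b: double-exponential
    (0.002, -0.001, c=4500) at n in {500, 250, 100, 50}. Experiment 4:
    double-exponential on the 3400-1850 window, c=2800, r1/r2 grids,
    n=288. Changepoint priors are uniform over the open window of each
    experiment. All with a fixed 20-year lab error and 20 replicates.
    """
    mcmc = mcmc or MCMCConfig(n_chains=1, n_iterations=10_000, n_burnin=3_000)
    designs = {}
    w1 = Window(6000, 4000)
    for r in (0.001, 0.003, 0.005):
        designs[f"exp1_r{r}"] = ExperimentDesign(
            name=f"exp1_r{r}", variant="exponential", true_params={"r": r},
            window=w1, n_dates=500, priors=_exp1_prior(), mcmc=mcmc,
        )
    for tag, (a, b) in {"steep": (7000, 6400), "plateau": (2800, 2200)}.items():
        designs[f"exp2_{tag}"] = ExperimentDesign(
            name=f"exp2_{tag}", variant="exponential", true_params={"r": 0.003},
            window=Window(a, b), n_dates=300, priors=_exp1_prior(), mcmc=mcmc,
        )
    for n in (250, 100, 50):
        designs[f"exp3a_n{n}"] = ExperimentDesign(
            name=f"exp3a_n{n}", variant="exponential", true_params={"r": 0.005},
            window=w1, n_dates=n, priors=_exp1_prior(), mcmc=mcmc,
        )
    for n in (500, 250, 100, 50):
        designs[f"exp3b_n{n}"] = ExperimentDesign(
            name=f"exp3b_n{n}", variant="double_exponential",
            true_params={"r1": 0.002, "r2": -0.001, "c": 4500},
            window=w1, n_dates=n, priors=_double_exp_priors(w1), mcmc=mcmc,
        )
    w4 = Window(3400, 1850)
    for r1 in (-0.001, -0.002, -0.003):
        for r2 in (0.001, 0.002, 0.003):
            designs[f"exp4_r1{r1}_r2{r2}"] = ExperimentDesign(
                name=f"exp4_r1{r1}_r2{r2}", variant="double_exponential",
                true_params={"r1": r1, "r2": r2, "c": 2800},
                window=w4, n_dates=288, priors=_double_exp_priors(w4), mcmc=mcmc,
            )
    return designs


# ---------------------------------------------------------------------------
# Recovery experiments


def simulate_dates(
    variant: str,
    true_params: dict,
    window,
    n_dates: int,
    curve: CalCurve,
    lab_error: float = 20.0,
    seed=None,
) -> list[C14Sample]:
    """Generate determinations from a growth model through the curve.

    Calendar dates are drawn from the model PMF and back-calibrated with
    the given lab error; lab codes are SIM-0001, SIM-0002, ...
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window = as_window(window)
    pmf = build_pmf(variant, window, true_params)
    theta = sample_calendar_dates(pmf, n_dates, rng)
    xs = _caldate.uncalibrate(theta.astype(float), curve, lab_error, rng)
    return [
        C14Sample(labcode=f"SIM-{j + 1:04d}", x=float(x), sigma_lab=float(lab_error))
        for j, x in enumerate(np.atleast_1d(xs))
    ]


@dataclass(frozen=True)
class RecoveryReport:
    """Per-replicate, per-parameter recovery results of one design.

    ``table`` columns: replicate, parameter, truth, median, hpd_lower,
    hpd_upper, covered. ``covered`` is True iff the true value lies inside
    the 90% HPD.
    """

    design: ExperimentDesign
    table: pd.DataFrame

    def coverage(self) -> pd.DataFrame:
        """Covered count and replicate total per parameter."""
        g = self.table.groupby("parameter")["covered"]
        return pd.DataFrame({"covered": g.sum().astype(int), "total": g.count()})

    def coverage_count(self, parameter: str) -> int:
        sub = self.table[self.table["parameter"] == parameter]
        return int(sub["covered"].sum())


def run_experiment(
    design: ExperimentDesign,
    curve: CalCurve,
    scale: float = 1.0,
    seed: Optional[int] = None,
    hpd_mass: float = 0.90,
) -> RecoveryReport:
    """Run a seeded parameter-recovery experiment.

    ``scale`` in (0, 1] shrinks the replicate count for desk-scale runs
    (at least one replicate always runs). Each replicate's random stream
    is spawned from (seed, replicate index), so results do not depend on
    execution order.
    """
    if not (0 < scale <= 1):
        raise ConfigError("scale must lie in (0, 1]")
    n_rep = max(1, int(round(design.n_replicates * scale)))
    free = [n for n in PARAM_NAMES[design.variant] if design.priors[n].is_free]
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_rep)
    rows = []
    for rep, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        samples = simulate_dates(
            design.variant, design.true_params, design.window, design.n_dates,
            curve, design.lab_error, rng,
        )
        fit_seed = int(rng.integers(2**31 - 1))
        config = dataclasses.replace(design.mcmc, seed=fit_seed)
        posterior = fit_mcmc(
            samples, design.variant, design.window, design.priors, curve, config
        )
        for name in free:
            hpd = hpd_interval(posterior.flat(name), hpd_mass)
            truth = float(design.true_params[name])
            rows.append(
                {
                    "replicate": rep,
                    "parameter": name,
                    "truth": truth,
                    "median": float(np.median(posterior.flat(name))),
                    "hpd_lower": hpd.lower,
                    "hpd_upper": hpd.upper,
                    "covered": truth in hpd,
                }
            )
    return RecoveryReport(design=design, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Case-study pipeline


def default_case_study_priors() -> dict:
    """Weakly informative priors for the m1/m2/m3 case-study fits.

    m1: r ~ Exponential(rate 2500), i.e. mean 0.0004 — the cross-cultural
    mean annual growth rate of prehistoric populations. m2 adds
    r1 ~ Normal(0, 0.0004) (decline as well as growth before the
    changepoint), r2 ~ Exponential(rate 2500) and
    c ~ TruncatedNormal(2625, 200, [1850, 3400]) (changepoint unlikely at
    the window edges). m3 keeps the m2 priors and puts
    k ~ TruncatedNormal(0.1, 0.1, [0.0001, 0.5]) on the initial proportion
    of carrying capacity.
    """
    m2 = {
        "r1": PriorSpec.normal(0.0, 0.0004),
        "r2": PriorSpec.exponential(2500.0),
        "c": PriorSpec.truncated_normal(2625.0, 200.0, 1850.0, 3400.0),
    }
    return {
        "m1": {"r": PriorSpec.exponential(2500.0)},
        "m2": m2,
        "m3": {**m2, "k": PriorSpec.truncated_normal(0.1, 0.1, 0.0001, 0.5)},
    }


_MODEL_VARIANTS = {"m1": "exponential", "m2": "double_exponential", "m3": "exp_logistic"}


@dataclass
class CaseStudyResult:
    """Everything the empirical pipeline produces."""

    samples: list
    filter_report: pd.DataFrame
    posteriors: dict
    summary: pd.DataFrame
    waic_table: pd.DataFrame
    envelopes: dict
    observed_spd: object
    window: Window


def case_study_pipeline(
    dates: Union[str, Path, Sequence[C14Sample], pd.DataFrame],
    curve: CalCurve,
    window=(3400, 1850),
    priors: Optional[dict] = None,
    mcmc: Optional[MCMCConfig] = None,
    models: Sequence[str] = ("m1", "m2", "m3"),
    n_ppc: int = 500,
    waic_draws: int = 500,
    seed: Optional[int] = None,
    max_error: float = 100.0,
    membership_threshold: float = 0.5,
) -> CaseStudyResult:
    """Filter, fit, diagnose, compare and check the empirical models.

    ``dates`` may be a CSV path (columns labcode, c14age, error[, site]),
    a DataFrame of the same shape, or a list of :class:`C14Sample`. Rows
    with a missing age or lab code are dropped, then rows with lab error
    above ``max_error`` 14C years, then dates whose calibrated mass inside
    the window (over the full curve) falls below ``membership_threshold``.

    The default MCMC protocol is three chains of 100,000 iterations with
    10,000 burn-in, thinned by 18 to retain 15,000 draws in total; pass a
    smaller :class:`MCMCConfig` for desk-scale runs.
    """
    window = as_window(window)
    priors = priors or default_case_study_priors()
    mcmc = mcmc or MCMCConfig(n_chains=3, n_iterations=100_000, n_burnin=10_000, thin=18, seed=seed)
    if mcmc.seed is None and seed is not None:
        mcmc = dataclasses.replace(mcmc, seed=seed)

    if isinstance(dates, (str, Path)):
        df = pd.read_csv(dates)
    elif isinstance(dates, pd.DataFrame):
        df = dates.copy()
    else:
        df = pd.DataFrame(
            {"labcode": [s.labcode for s in dates], "c14age": [s.x for s in dates],
             "error": [s.sigma_lab for s in dates],
             "site": [s.site for s in dates]}
        )
    # hygiene filters: missing age / missing lab code / error above cutoff
    df = df.dropna(subset=["c14age"])
    df = df[df["labcode"].notna() & (df["labcode"].astype(str).str.strip() != "")]
    df = df[df["error"] <= max_error]
    samples = [
        C14Sample(
            labcode=str(r.labcode), x=float(r.c14age), sigma_lab=float(r.error),
            site=None if not hasattr(r, "site") or pd.isna(r.site) else str(r.site),
        )
        for r in df.itertuples(index=False)
    ]
    kept, report = window_filter(samples, curve, window, membership_threshold)
    if len(kept) == 0:
        raise InsufficientDataError("no dates survive the hygiene and window-membership filters")

    calibrated = [calibrate_date(s, curve, window) for s in kept]
    observed = spd(calibrated, normalize=True)
    errors = [s.sigma_lab for s in kept]

    root = np.random.SeedSequence(seed)
    sub_seeds = root.spawn(len(models) * 3)
    posteriors, envelopes, summaries, waics = {}, {}, [], []
    for m_i, m in enumerate(models):
        variant = _MODEL_VARIANTS[m]
        config = dataclasses.replace(mcmc, seed=int(np.random.default_rng(sub_seeds[3 * m_i]).integers(2**31 - 1)))
        post = fit_mcmc(kept, variant, window, priors[m], curve, config)
        posteriors[m] = post
        st = summary_table(post)
        st.insert(0, "model", m)
        summaries.append(st)
        ll = pointwise_loglik(post, kept, curve, n_draws=waic_draws, seed=np.random.default_rng(sub_seeds[3 * m_i + 1]))
        waics.append(waic(ll, name=m))
        envelopes[m] = posterior_predictive_spd(
            post, len(kept), errors, curve, observed_spd=observed,
            n_sim=n_ppc, seed=np.random.default_rng(sub_seeds[3 * m_i + 2]),
        )
    return CaseStudyResult(
        samples=kept,
        filter_report=report,
        posteriors=posteriors,
        summary=pd.concat(summaries, ignore_index=True),
        waic_table=compare(waics),
        envelopes=envelopes,
        observed_spd=observed,
        window=window,
    )


# ---------------------------------------------------------------------------
# Reproducibility manifest


def manifest(seed, config: Optional[dict] = None, curve: Optional[CalCurve] = None) -> dict:
    """Seed + config hash + curve checksum: enough to reproduce a run."""
    out = {"seed": seed}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        out["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if curve is not None:
        h = hashlib.sha256()
        for arr in (curve.calbp, curve.mu, curve.tau):
            h.update(np.ascontiguousarray(arr).tobytes())
        out["curve_sha256"] = h.hexdigest()
    return out
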