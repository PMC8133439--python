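# c14growth

Bayesian fitting and comparison of demographic growth models for the
time-frequency of radiocarbon dates.

## The problem

Archaeologists and paleodemographers use large collections of radiocarbon
(¹⁴C) determinations as a proxy for past population size: more people leave
more datable material, so the density of dates through time tracks relative
population. The conventional summary — the summed probability distribution
(SPD) of calibrated dates — is easy to compute but hard to interpret, because
sampling error and the wiggles of the calibration curve create peaks and
troughs that have nothing to do with demography. Fitting growth models
directly to an SPD by regression ignores both sources of error and biases
every downstream statistic.

`c14growth` instead treats time as **discrete** and models each date's true
calendar year θⱼ as a draw from a *bounded growth model*: a categorical
(generalised Bernoulli) distribution over the calendar years of an analysis
window [b, a] (cal BP, a older), whose shape follows a demographic
trajectory. With the standard Gaussian measurement model this gives a full
hierarchical model

```
θⱼ ~ BoundedGrowth(a, b, params)
Xⱼ ~ Normal(μ(θⱼ), σⱼ),      σⱼ² = σ_lab,ⱼ² + τ(θⱼ)²
```

where μ(t) ± τ(t) is the calibration curve (e.g. IntCal20) and Xⱼ ± σ_lab,ⱼ
the observed ¹⁴C age. Because θⱼ lives on a finite yearly grid, the
likelihood is exactly computable; the package samples the posterior of the
growth parameters by adaptive random-walk Metropolis–Hastings, summarises it
with highest-posterior-density (HPD) intervals, Gelman–Rubin R̂ and effective
sample size, compares competing growth models with WAIC, and checks fitted
models against the observed SPD with posterior-predictive simulation
envelopes.

Three growth-model families are built in (any positive trajectory Nₜ can
also be supplied directly):

- **exponential** — `p_{t=a-i} ∝ (1+r)^i`, a single annual rate `r`;
- **double-exponential** — rate `r1` before a changepoint year `c`, `r2`
  after (peaks exactly at `c` when `r1 > 0 > r2`);
- **exponential–logistic** — exponential at rate `r1` until `c`, then a
  logistic approach to carrying capacity with intrinsic rate `r2`;
  `k ∈ (0,1)` is the initial population as a proportion of that capacity.

A simulation workbench replays seeded parameter-recovery experiments
(sample calendar dates → back-calibrate through a curve → calibrate → fit →
score 90% HPD coverage) so users can ask, *before* analysing real data,
whether their sample size and window can support the model they care about.

## Worked example

Simulate 300 dates from exponential growth at r = 0.003 over 6000–4000
cal BP through an identity calibration curve (τ = 20 ¹⁴C yr), then refit:

```python
import c14growth as cg

curve = cg.synth_curve("identity", (3500, 6500), tau0=20.0)
window = cg.Window(6000, 4000)
samples = cg.simulate_dates("exponential", {"r": 0.003}, window, 300,
                            curve, lab_error=20.0, seed=42)
config = cg.MCMCConfig(n_chains=2, n_iterations=5000, n_burnin=1000,
                       thin=4, seed=42)
post = cg.fit_mcmc(samples, "exponential", window,
                   {"r": cg.PriorSpec.exponential(500)}, curve, config)
print(cg.summary_table(post).to_string(index=False))
```

which prints

```
parameter     Rhat         ESS   Median  HPD90lower  HPD90upper
        r 1.000185 1402.129845 0.002916    0.002631    0.003209
```

The posterior median annual growth rate is 0.0029 (0.29% per year) and the
90% HPD interval [0.00263, 0.00321] covers the generating value 0.003; R̂
at 1.0002 and an ESS of ~1400 indicate the two chains mixed well at this
desk-scale iteration count. Longer runs (the empirical protocol is three
chains of 100,000 iterations, 10,000 burn-in, thinned to 15,000 draws)
drive R̂ under 1.001.

The same workflow is available from the shell:

```
c14growth simulate design.yaml --out dates.csv --curve identity:3500-6500 --seed 1
c14growth fit dates.csv --model design.yaml --out posterior.csv --curve identity:3500-6500
c14growth experiment design.yaml --out report.csv --seed 1
```

Calibration curves are read from the standard `.14c` comma-separated format
(`#` comments; columns CAL BP, ¹⁴C age, error), so a downloaded IntCal20
file can be passed wherever a curve is expected; a synthetic wiggle curve is
bundled for download-free work, and `synth_curve` makes identity / linear /
plateau / steep / wiggle curves on demand. Calendar convention throughout:
0 cal BP = 1950 CE, BCE = BP − 1950 + 1.

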