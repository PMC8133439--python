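# Methods

## Model

Time is discrete at one-year resolution. An analysis window [b, a]
(calendar years BP; a older than b; both fixed, user-chosen constants)
indexes years as i = a − t, i = 0 … T with T = a − b. A *bounded growth
model* assigns each year a probability p_t ≥ 0 with Σ p_t = 1 and p_t = 0
outside the window; it is the categorical distribution from which each
sample's true calendar date θ_j is drawn. The observed ¹⁴C age follows the
Gaussian measurement model X_j ~ Normal(μ(θ_j), σ_j), where μ(t) is the
calibration curve and σ_j² = σ_lab,j² + τ(t)² combines the reported lab
error with the curve error at t in quadrature.

Growth families:

- **Exponential**: p_{t=a−i} ∝ (1+r)^i. The normalising constant is the
  geometric sum, so only r matters; r = 0 is the uniform phase model.
- **Double-exponential**: annual rate r(t) = r1 for t > c, r2 for t ≤ c,
  with the trajectory stepping N_{t−1} = N_t (1 + r(t)). Under this
  source-year rule the trajectory is continuous through the handover and,
  for r1 > 0 > r2, peaks exactly at the changepoint c. c enters as a real
  number; the comparison t > c is applied to integer years directly, which
  keeps the likelihood piecewise-constant-free (continuous) in c during
  MCMC.
- **Exponential–logistic**: k(1+r1)^i for t > c and
  [1 + ((1−K)/K) e^{−r2 i}]^{−1} for t ≤ c, with K = k(1+r1)^{a−c} and the
  global index i in the exponent. As written this trajectory has a small
  discontinuity at t = c; the option `changepoint_relative=True` measures
  the exponent from the changepoint (e^{−r2 (i−(a−c))}), which makes it
  continuous. The default keeps the global-index form, the family's usual
  printed definition. The constraint K < 1 is enforced (otherwise the
  logistic fraction is undefined) and violations during sampling are
  treated as zero-prior proposals.
- **Trajectory**: any positive N_t vector, normalised.

All builders evaluate in log space and normalise by max-shifted
exponentiation (equivalent to log-sum-exp), so rates up to ~0.01 on
windows of 10,000 years stay finite.

## Likelihood and sampler

Because θ_j is discrete on a finite grid it is summed out exactly: the
per-date marginal likelihood is Σ_t p_t Normal(X_j; μ(t), σ_j(t)). The
Normal factors depend only on the data and curve, so they are precomputed
once as an (n × T+1) matrix with per-row scaling; each likelihood
evaluation afterwards is a single matrix–vector product. The sampler is an
adaptive univariate random-walk Metropolis–Hastings on the growth
parameters against this collapsed posterior. Latent dates are not imputed
during parameter updates; when requested they are drawn exactly from their
categorical full conditional p(θ_j = t | ·) ∝ p_t · Normal(X_j; μ(t), σ_j(t))
at retained iterations. The joint target is identical to a scheme that
alternates parameter MH with per-date Gibbs updates, but collapsing mixes
better and is far cheaper per iteration.

Adaptation rescales each parameter's proposal SD every 200 iterations
toward a target acceptance rate of 0.44 with a Robbins–Monro gain decaying
as 1/√(rounds) — diminishing adaptation, so the chain remains valid.
Initial values are drawn from the priors until the posterior is finite
(200 attempts, then an initialisation error). Chains are spawned from a
`SeedSequence` of the user seed; identical seed and config give bitwise
identical draws. Proposals outside a parameter's domain (r ≤ −1, c outside
the open window, K ≥ 1) get −∞ log posterior and are rejected.

## Priors

`PriorSpec` supports exponential (parameterised by **rate** λ; mean 1/λ),
normal, truncated normal (renormalised by in-bounds mass), uniform, and
fixed. The case-study defaults are weakly informative: for the exponential
model r ~ Exponential(λ = 2500), i.e. mean 0.0004, the cross-cultural mean
annual growth rate of prehistoric populations; for the changepoint models
r1 ~ Normal(0, 0.0004) (decline as plausible as growth before the shift),
r2 ~ Exponential(2500), c ~ TruncNormal(2625, 200, [1850, 3400]) (a
changepoint unlikely at the window edges), and
k ~ TruncNormal(0.1, 0.1, [0.0001, 0.5]) for the initial proportion of
carrying capacity. The simulation-experiment presets use
r ~ Exponential(λ = 500) for exponential fits, Normal(0, 0.1) for the
double-exponential rates and a uniform changepoint prior over the open
window of each experiment (the 3400–1850 experiments use Uniform(1851,
3399), bounds matching their own window).

## Calibration conventions

- Curves are stored at their published knots, sorted oldest-first, and
  linearly interpolated (both μ and τ) to a one-year grid before use —
  standard practice for calibration software.
- Calibration for likelihood use normalises within the analysis window.
  The window-membership filter, by contrast, calibrates over the full
  curve span and measures the cumulative mass inside the window; samples
  with mass ≥ 0.5 (inclusive) are retained by default, so only dates
  strictly below threshold drop out. A calibrated mass whose best log
  density is below log(DBL_MIN) ≈ −745 is reported as degenerate rather
  than silently renormalised.
- Back-calibration draws one Normal with variance τ² + σ_lab² — the
  curve-draw-then-counting-noise two-stage scheme collapsed, since the two
  Gaussians are independent.
- 0 cal BP = 1950 CE; BCE = BP − 1950 + 1 (2664 BP = 715 BCE).

## Diagnostics and model comparison

- **HPD**: shortest contiguous window of the sorted draws containing
  ⌈mass·n⌉ of them. This assumes unimodality; a crude histogram-valley
  heuristic warns when the sample looks strongly multimodal, but the same
  rule is still applied.
- **Gelman–Rubin**: R̂ = √((W₀ + B/n)/W₀) with W₀ the mean within-chain
  variance (denominator n) and B = n·var(chain means). This pooled-versus-
  within form gives exactly 1.0 for identical chains; it is the classic
  two-variance PSRF without rank-normalisation or chain-splitting,
  matching the original diagnostic and the conventional ≤ 1.001 threshold.
- **ESS**: n / (1 + 2 Σ ρ_k), FFT-estimated autocorrelations summed in
  consecutive pairs while each pair sum is positive (initial-positive-
  sequence truncation) — stable on thinned chains. Summaries report the
  ESS summed over chains.
- **WAIC**: lppd − p_waic on pointwise log likelihoods, WAIC = −2(lppd −
  p_waic), variance penalty with ddof = 1. The pointwise likelihood is the
  **marginal** per-date likelihood (θ summed out at each retained draw of
  the growth parameters), giving a well-defined observation-level
  predictive density independent of latent imputation; a
  conditional-on-imputed-θ variant would produce different absolute WAIC
  values, though typically similar differences. Model weights are
  exp(−Δ/2), normalised (Akaike convention), reported in a table sorted
  by WAIC.

## Posterior-predictive checks

For each of n_sim (default 500) iterations: draw one posterior parameter
combination, build its PMF, sample n_dates calendar years, back-calibrate
each with a lab error resampled with replacement from the observed errors,
calibrate, and sum to a normalised SPD. The envelope is the pointwise
2.5%/97.5% quantile band (per-year, not simultaneous). Coverage reports
the fraction of years where the observed SPD lies inside the inclusive
band plus the out-of-band years split by sign. A `calsample`-style option
skips the measurement-noise draw (the smear is curve+lab error only); it
is a best-effort reconstruction of that alternative algorithm and is not
used by any acceptance check.

## Synthetic data and what it does not emulate

`synth_curve` provides identity, linear, plateau, steep and wiggle curves
with constant τ; plateau and steep mimic the calibration-curve features
known to distort inference, and the identity curve makes calibration an
exactly discretised Normal, which is used as the analytic oracle in tests.
`simulate_dates` replays the full generative chain of the model. What the
synthetic data do **not** contain: real calibration-curve error structure
(τ varying with t, correlated knot errors), heaped lab errors, inter-site
sampling-intensity variation, reservoir effects, or curatorial selection —
so passing recovery tests demonstrate correctness of the inferential
machinery under the model's own assumptions, not robustness to the ways
real archives violate them.

## Problem sizes

Desk-scale defaults were chosen so the full test suite and the acceptance
script each run in minutes on one CPU: recovery experiments use 20
replicates of n = 300 dates with single chains of 5,000 iterations (1,250
burn-in) for the one-parameter exponential model, which converges far
faster than the multi-parameter families; the changepoint demonstration
uses n = 288 dates and 10,000 iterations. The empirical-analysis default
in `case_study_pipeline` remains the full protocol (three chains ×
100,000 iterations, 10,000 burn-in, thinned by 18 to 15,000 retained
draws).

## Known limitations

- Window boundaries a, b are constants, never inferred; edge effects are
  handled only through the membership filter.
- No binning or pooling of same-context dates; dates are assumed
  independent given the growth model.
- Marine calibration curves, reservoir offsets and post-bomb curves are
  out of scope.
- The HPD estimator is misleading for genuinely multimodal posteriors
  (it still returns the shortest single interval).
- WAIC absolute values depend on the marginal-likelihood convention above;
  compare models only within one convention.
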