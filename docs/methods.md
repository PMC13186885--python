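# Methods

## Scope and model

The package studies what happens to parameter inference when the
*independent* variable — time, in all five case studies — is recorded with
error, and the fit ignores it. Responses are always generated from the
hidden true time `x`; the naive fit sees only the recorded `w`. Two
mechanisms are implemented as first-class objects (`ErrorSpec`):

* classical, `w = x + u`: the observation scatters about the truth;
* Berkson, `x = w + u`: the truth scatters about the recorded value.

Errors are non-differential (the error distribution does not depend on the
response), additive, and either normal (parameterised by **variance**
`var_u`) or uniform on `[0, Δ]` (biased — the event always happens *after*
the protocol time, as with a dosing delay) or `[-Δ/2, Δ/2]` (unbiased).
Equation error ε (scatter of the response about the deterministic model)
is kept distinct from timing error and may be additive or multiplicative,
`y = (1 + ε)f(x)`.

A note on conventions: the linear and oscillator study tables state their
normal distributions as N(mean, **variance**) — so the linear designs use
timing and equation error variance 0.25 and the oscillator designs 0.05.
This reading is internally consistent: the attenuation factor
λ = 1/(1+0.25) = 0.8 and the amplitude attenuation 3e^{-8·0.05} ≈ 2.01
both match the reference estimates only under the variance convention.
Where a symbol is explicitly a standard deviation (parasite σ_U = 0.25
days; tumour growth rate r ~ N(0.08, 0.02²)) it is honoured as one.

## The five generators and what they emulate

All generators return a `TimecourseDataset` holding observed `(w, y)`
pairs *and* the hidden truth (true times, per-subject parameters), so any
fit can be run against either pairing. Defaults are the study conditions;
a seeded `numpy` Generator (or integer seed) makes every dataset
reproducible bit-for-bit.

1. **Linear** (`Y = β₀ + βₓX + ε`, truth β₀=0, βₓ=1, n=50): non-controlled
   classical (X ~ N(0,1)), non-controlled Berkson (W ~ N(0,1)), and
   controlled Berkson (five protocol points on [-2, 2], ten replicates
   each). Timing and equation error variance 0.25.
2. **Oscillator** (`Y = a·cos(bX) + ε`, a=3, b=4, n=50): classical and
   Berkson non-controlled designs with X or W ~ U(-2,2), and two
   controlled designs — five points on [-2, 2] (case 1) and five points
   spaced π/4 on [-π/2, π/2] (case 2), the latter aligned with turning
   points of cos(4x) so the amplitude is observed directly. Error
   variances 0.05. Case 2 admits a closed-form oracle: the naive amplitude
   estimator has mean `a·E[cos(4U)] = a·e^{-8 var_u}`.
3. **Parasite growth** (`P(t) = V₀e^{gt} + B₀e^{-kt}`; V₀=0.002, g=0.531,
   B₀=0.02, k=0.323, per day): one measurement per protocol day
   {0, 2, …, 24}; the true time is the day plus N(0, σ_U²) (σ_U = 0.25
   days default — only the day is recorded); the response carries a
   multiplicative equation error. Negative responses possible at large σ_ε
   are kept: nothing in the design censors them.
4. **Tumour cohort** (Gompertz; y(0) ~ U(100, 120), r ~ N(0.08, 0.02²),
   K=4000; six tumours, days {0, 2, …, 60}): tumour volume is measured
   exactly, but the tumours are measured *sequentially* each day, one
   experimentalist, each measurement lasting a lognormal duration with
   mean 1/6 day and SD 0.1 day. The delay of the T-th tumour measured is
   the cumulative sum of the first T durations (its own included).
   Ordering is fixed or reshuffled per day. The r ~ N(0.08, 0.02²) draw is
   resampled in the ≤4·10⁻⁵ tail r ≤ 0, which the Gompertz form cannot
   accept.
5. **GLUT4 translocation** (`P(t) = (P₀-M)e^{-kt} + M`, minutes; protocol
   times {0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60}): the dose lands
   U ~ U(0, Δ) minutes late; responses are lognormal with original-scale
   mean P(θ, t) and variance σ_Y², via the exact moment map
   μ = ln(m²/√(m²+σ_Y²)), σ² = ln(1+σ_Y²/m²). The plateau M is stored as a
   free parameter: the study's parameter grid takes M up to 29 even though
   the two-compartment derivation with P+S=1 would bound it by 1, so the
   proportionality constraint is deliberately not enforced (the optional
   k_en/k_ex decomposition is validated when supplied).

What the generators do **not** emulate: dependent-variable measurement
error as distinct from equation error (the two are conflated in ε, as is
standard when the response error is additive), differential errors,
multiplicative time errors `W = XU`, model misspecification, and real
biological covariance structure beyond the stated heterogeneity. Passing
tests therefore demonstrate properties of inference under exactly these
error mechanisms, not robustness of any particular laboratory pipeline.

## Naive inference

`fit_least_squares` minimises the residual sum of squares with a bounded
trust-region solver; lower bounds enforce sign constraints
(non-negative rates, amplitudes, volumes). When the model is linear in its
free parameters (the line; the cosine amplitude with frequency fixed) the
normal-equations solution is computed exactly instead — same estimator,
no iteration. Covariance is `(JᵀJ)⁻¹s²` from the Jacobian at the optimum;
confidence bounds are `b ± t·√S` with `t` the Student quantile at `n-p`
degrees of freedom. Singular or ill-conditioned `JᵀJ` falls back to a
pseudo-inverse and flags the result — the parasite background parameters
(B₀, k) are the canonical non-identifiable example. Non-convergence flags
the result rather than raising, so replicated studies can count failures.

Default starts are data-driven but deliberately generic (parasite:
(V₀, g, B₀, k) = (0.01, 0.3, 0.01, 0.5)); the replicated parasite grid
starts each cell's fits at the generating truth, since cells are
replicated 100–1000× and the quantity of interest is the estimator
distribution, not optimiser robustness. The KDE uses a Gaussian kernel
with the normal-reference (Silverman) bandwidth.

## Bayesian layer

The GLUT4 study uses the naive lognormal likelihood evaluated at recorded
protocol times. Because replicates at the same protocol time share one
lognormal, the likelihood collapses to per-time sufficient statistics
(count, Σln y, Σ(ln y)²) — an exact algebraic identity kept dual-routed in
the tests against the per-observation sum.

The posterior is approximated by adaptive likelihood-tempered SMC:
particles start from the prior; each temperature increment is chosen by
bisection so the conditional effective sample size stays near
`ess_target·N` (default 0.5); systematic resampling then `n_moves = 5`
random-walk Metropolis–Hastings steps with proposal covariance
`(2.38²/d)·Σ̂` adapted from the weighted cloud. The ladder always ends at
temperature 1. Defaults (N=1000 particles) are this package's choices —
the tempered-SMC recipe is standard, and every knob is exposed. Priors
default to independent uniforms on [0, 2×grid-max] per parameter
(P₀, k ∈ [0, 0.5]; M ∈ [0, 58]), again a documented choice. The MAP is the
particle maximising prior × likelihood (deterministic given the particle
set, unlike a KDE mode); credibility intervals are equal-tailed weighted
marginal 2.5–97.5 percentiles. Reported metrics per parameter: |MAP −
truth|, interval width, and distance from the truth to the interval (zero
when covered).

## Corrections

* **Reliability ratio** λ = σₓ²/(σₓ²+σᵤ²); corrected slope = naive/λ.
  Exact for linear models with known classical error variance.
* **Fuller's method of moments**: slope = S_wy/(S_ww − σᵤ²), degenerate
  when the sample variance of `w` does not exceed σᵤ². Algebraically a
  reliability-ratio correction with λ estimated from the same moments.
* **Regression calibration**: impute `E[X|W]`; the best-linear form
  x̂ = μₓ + λ(w − μₓ). For unbiased Berkson error `E[X|W] = W` — the
  imputation is the identity and nothing is gained.
* **Orthogonal regression**: joint minimisation of
  Σ[(yᵢ − f(θ, xᵢ))² + η(wᵢ − xᵢ)²] over θ and the N latent abscissae,
  η = σ_ε²/σᵤ², solved as one sparse-Jacobian least-squares problem. The
  η = 1 special case is scale-dependent (rescaling the response changes
  the correction) and ignores equation error — this known overcorrection
  is surfaced in the docstring and asserted in the tests rather than
  patched.
* **SIMEX**: refit under inflated error `w + √ζ·N(0, σᵤ²)` for
  ζ ∈ {0.5, 1, 1.5, 2} (B pseudo-datasets per ζ, default 100), then
  extrapolate the estimate trajectory to ζ = −1. Both a quadratic and a
  rational-linear extrapolant `a + b/(c+ζ)` are provided; the latter is
  exact for the linear attenuation curve λ(ζ) = σₓ²/(σₓ²+(1+ζ)σᵤ²) and is
  fitted from several starting values with quadratic fallback on failure
  or a pole at ζ = −1.
* **Marginal ME likelihoods**: per observation,
  classical φ(y|w) = ∫φ(y|x)φ(w|x)φ_X(x)dx (a latent-X density is
  required); Berkson φ(y|w) = ∫φ(y|x)φ(x|w)dx (no density for the
  recorded values is needed — they carry no information in a controlled
  experiment). Normal latent errors use Gauss–Hermite quadrature, uniform
  Berkson errors Gauss–Legendre on the support. The default order 21 is
  accurate (≲1e-9 vs adaptive integration) for mildly nonlinear
  integrands; strongly oscillatory ones — the cosine model with b = 4 —
  need a few hundred nodes, so the order is a first-class setting and the
  oscillator bias-removal analyses use order ~300. Zero-density
  observations return −∞; a zero error variance reduces exactly to the
  naive likelihood (plus, for classical error, the θ-independent
  log-density of the recorded values).
* **Method chooser**: a deterministic rule table ranking the above by the
  data situation (model class, extra data, known variance, error
  mechanism, fully specified distribution), with literature pointers;
  validation-data methods are reference-only stubs.

## Replicated studies and problem sizes

`run_study` wires generators and fitters into named experiments emitting
tidy long-format tables (replicate × scenario × parameter). Default
replicate counts mirror the study designs — 1000 (linear), 10000
(oscillator, tumour), 1000 per parasite grid cell — with a `scale` factor
for quick runs. The test suite uses scaled-down sizes chosen so
Monte-Carlo error stays well under the effects being asserted: 1000
replicates for the linear, oscillator and tumour resampling checks, a
10×10 parasite grid at 100 replicates per cell, 100 replicates for the
correction consistency checks, and 20 seeds × 4 heterogeneity levels for
the GLUT4 monotonicity check. Randomness is always routed through
`numpy.random.SeedSequence` spawning, so every study is reproducible from
one root seed and replicates are independent.

## Numerical choices and known limitations

* Trust-region least squares runs at machine-precision tolerances; the
  linear-in-parameters shortcut makes the OLS-oracle agreement exact to
  ~1e-12 and the replicated studies cheap.
* The rational SIMEX extrapolant can be ill-posed when the trajectory is
  nearly affine; the quadratic fallback is logged in the result flags.
* The finite-sample ML amplitude estimator under the Berkson marginal
  likelihood carries a small (~0.5% at n=50) downward bias; it vanishes
  with n and is within the Monte-Carlo band of the bias-removal checks.
* Parasite fits at extreme equation error (σ_ε ≳ 0.3 with only 13 points)
  produce heavy-tailed estimator distributions; grid summaries report
  means and variances of whatever the estimator does, including those
  tails.
* SMC credibility intervals are marginal and equal-tailed; joint coverage
  is not assessed. The sampler assumes the likelihood is cheap enough to
  evaluate for the full particle cloud at every tempering step, which the
  sufficient-statistic collapse guarantees for the GLUT4 study.
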