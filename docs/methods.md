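# Methods

This note documents the models behind `lambdaslider`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing its output.

## Utility model and slider geometry

A respondent's utility for an allocation (w_s, w_t) is

    u = w_s + λ w_t − κ |w_s − w_t| ,     κ ∈ [0, 1),

with λ the welfare tradeoff ratio toward the target and κ the weight on
inequity aversion.  On a quadratic slider (w_s = −a x² + b_s,
w_t = 2 a x + b_t, x ∈ [x_min, x_max]) the utility is piecewise quadratic
and concave on each branch; the global optimum is one of

- the branch vertices (λ+κ)/(1−κ) (where w_s ≥ w_t) and (λ−κ)/(1+κ)
  (where w_s < w_t), clipped to the range,
- an equal-payoff breakpoint (root of w_s = w_t), or
- a range bound.

`optimal_position` evaluates the exact utility at this candidate set, which
is provably exhaustive, so the optimizer is exact (tested against a
100 001-point grid).  With κ = 0 the optimum reduces to clip(λ), the
identity that makes the slider a single-response measure of λ.  When the
parabola/line intersection has two in-range roots, `equal_payoff_point`
returns the larger and exposes both through `equal_payoff_roots`.

Raw on-screen positions χ ∈ [0, 1] are treated as continuous (pixel
quantization is ignored) and map affinely to the λ scale,
x = (1−χ)x_min + χx_max.

## Response policies and censoring

Two stochastic response accounts are implemented:

- **utility policy** ("Hlambda"): x = clip(x* + ε), ε ~ N(0, σ_e²) on the
  λ scale;
- **anchor policy** ("Hchi"): χ = clip(χ_anchor + ε), ε ~ N(0, σ_χ²) on the
  raw scale, ignoring the payoffs.

The Gaussian-plus-clipping form is this package's choice of noise process;
nothing in the measurement theory prescribes a distribution.  A response
that lands exactly on a bound is flagged **censored** (for imported data,
within 1e-6 of the bound) and carries only one-sided information; every
estimator treats it as such.

## Estimators

**Identity readout.**  An interior response position is the λ estimate; a
censored one is reported as a one-sided bound.

**Two-slider inversion.**  With one uncensored response x₁ on a slider
where w_s > w_t throughout and x₂ where w_s < w_t,

    λ = (x₁ + x₂ + 2x₁x₂)/(2 + x₁ + x₂),   κ = (x₁ − x₂)/(2 + x₁ + x₂),

valid (κ ∈ [0,1)) iff x₁ ≥ x₂ > −1 or x₁ ≤ x₂ < −1; x₁ + x₂ = −2 (the
λ = −1 line) is degenerate and raises.  Otherwise the mean of the two
positions is returned as a fallback λ estimate with no κ.

**Reliability.**  For n averaged parallel measurements the reliability
odds scale linearly: ρ′/(1−ρ′) = n ρ/(1−ρ).

**Censored multivariate normal.**  Test–retest and convergent-validity
correlations are estimated by a Bayesian MVN fit in which a cell at a
bound contributes the conditional tail probability given the row's
observed cells (normal CDF for one censored cell, bivariate-normal CDF via
a 48-node Gauss–Legendre angular quadrature for two, and the
Mendell–Elston sequential-conditioning approximation for the rare rows
with three or more).  Priors: wide zero-centered normals on means,
half-Cauchy on scales, and uniform over valid correlation matrices
(canonical partial correlations with the matching symmetric-Beta priors).
Sampling uses the emcee ensemble sampler with differential-evolution
moves; walkers double as chains for a split-R-hat diagnostic (recorded on
the summary; values ≲ 1.05 are typical at the default 900 steps).
Summaries are posterior medians with 95% equal-tailed intervals.  Fully
observed rows enter through sufficient statistics, and a batched
likelihood path evaluates whole walker ensembles at once.

**Hierarchical λ/κ.**  Each participant has one κ ∈ [0, 0.95] (uniform
prior) and one λ per target (N(0, 2²) prior); the likelihood of a response
is a censored normal around the exact optimum for the candidate (λ, κ).
Because participants are conditionally independent, the posterior is
computed by exact grid quadrature (λ step 0.01 on [−4, 4], κ step 0.01)
rather than MCMC — deterministic, fast, and free of convergence concerns.
The response-noise σ_e defaults to a method-of-moments estimate from
repeat pairs, Var(x₁−x₂) = 2σ², floored at 0.02.  Identification caveat:
a respondent with large κ is pushed past the bounds of the offset sliders,
leaving only inequality information; such participants get honestly wide κ
intervals, and their λ posteriors inherit the ridge.  At the default panel
scale (76 × 6 × 3 sliders × 2 repeats, σ_e = 0.3) the fit recovers κ with
rank correlation ≈ 0.95 and λ with mean absolute error ≈ 0.17.

**Distance trend.**  The outcome is regressed on the social-distance rank
(ordinal, never metric) through a monotone effect: total drop b₃ (K−1)
times the cumulative sum of a simplex of per-rank increments (softmax
parameterization, standard-normal priors on the unconstrained weights), a
participant random intercept, and Gaussian noise.  Without bounds the
intercept is marginalized in closed form; with bounds, boundary outcomes
contribute censored tail terms and the intercept is integrated by 15-node
Gauss–Hermite quadrature (ignoring censoring attenuates the slope
noticeably).  b₃ is the mean per-rank slope; fitted rank means are
monotone by construction, in the direction of b₃'s sign.  Note the
monotone effect treats the realized per-rank means of a finite panel as
the estimand, so with a truly flat population the interval occasionally
excludes zero when sampling noise produces a monotone drift.

## Model comparison (utility vs anchoring)

If responding is utility-based, the same λ implies different raw positions
on range-shifted sliders: χ_B = (width_A χ_A + x_min,A − x_min,B)/width_B
(a constant offset, 0.1875, for the shipped equal-width shifted set).  If
responding anchors on the raw position, χ_B = χ_A.  `compare_models` fits
a censored 6-variate normal (2 repeats × 3 sliders per participant–target,
raw scale) under each account's mean constraint — one free population mean
(λ̄ under the utility account, χ̄ under the anchor account, priors matched
through the slider width so the models are comparable) — and a covariance
shared across models: one scale per slider (common to its repeats), one
within-slider and one between-slider correlation.  The structured
covariance is a deliberate simplification; the mean structure carries all
the evidence that separates the accounts.  Evidence is the difference in
log marginal likelihoods from bridge sampling (Meng–Wong optimal bridge
against a moment-matched Gaussian proposal), with the maximized
log-posterior difference reported alongside as a cheap cross-check (the
models have equal dimensionality, so this is the BIC difference up to a
constant).  On synthetic panels at the default scale the two accounts
separate by hundreds of log units, and the sign identifies the generator
in every seeded replicate tested.

## Synthetic panels

`generate_panel` draws, per participant p and target t of rank r,

    λ_pt = m_r + u_p + v_pt,   u_p ~ N(0, σ_p²),   v_pt ~ N(0, σ_t²),

with nonincreasing rank means m_r (rank 1 = socially closest), a
per-participant κ from a mixture of a point mass at 0 (weight 0.4) and a
uniform component on (0.05, 0.95), and then simulates slider responses
under either policy.  Default configurations:

- **reliability panel**: 30 participants × 10 targets × 1 slider × 2
  repeats, κ ≡ 0, m_r linear from +0.86 to −0.86.  With σ_p = 0.7,
  σ_t = 0.5 the true-score variance is ≈ 1.04, so σ_e = 0.42 puts the
  single-response test–retest correlation at ≈ 0.86 and the marginal
  response sd at ≈ 1.1 — the regime the instrument is designed for.
- **range-shift panel**: 16 × 10 × 3 range-shifted sliders × 2 repeats,
  raw-scale noise 0.05 (0.2 on the λ scale), policy selectable.
- **inequity panel**: 76 × 6 × 3 offset sliders (a = 7) × 2 repeats,
  σ_e = 0.3, κ from the mixture.

Shipped slider fixtures: the reference design (a = 11.25, b_s = 70,
b_t = 50, x ∈ [−2, 2], payoffs w_s ∈ [25, 70], w_t ∈ [5, 95]); equal-width
shifted ranges [−1.25, 2.75] and [−2.75, 1.25] with (b_s, b_t) = (90, 33)
and (90, 67), re-derived so payoffs stay inside the 0–100 display; and an
a = 7 set on [−2, 2] — balanced (60, 45), self-more (95, 30, w_s > w_t
everywhere, margin 9) and target-more (35, 70, w_s < w_t everywhere,
margin 28).  The offset-sign conditions are checked by tests.

The donation decision is a dictator-style split of a 2-unit endowment:
the deterministic optimum of u(d) = (2−d) + λd − κ|2−2d| is d = 0, the
equal split, or 2 (equal split wins iff 1−2κ < λ < 1+2κ), plus truncated
Gaussian noise.  This generative link between (λ, κ) and the donation is
the package's construction for testing the qualitative external-validity
pattern (donations rise with λ; distance from the equal split falls with
κ); it is not a claim about how real donations arise.

What the generator does **not** emulate: attention failures and exclusion
logistics, item-order or anchoring-on-initial-position effects, nonlinear
payoff-to-welfare mappings, response-time dynamics, or per-decision
switching between selfishness and pure equality seeking.  Passing
recovery tests therefore demonstrates internal consistency of the
estimators under the stated noise model, not robustness to these human
behaviors.

## Numerical choices

- Posterior summaries are medians with 95% equal-tailed intervals
  throughout.
- Censoring tolerance for imported data: |x − bound| < 1e-6.
- The bivariate normal CDF uses the single-integral angular form with
  48 Gauss–Legendre nodes (|ρ| clipped at 0.999; accuracy ~1e-8).
- Mendell–Elston is used only for rows with ≥ 3 censored cells (a few
  percent of rows at most in the shipped configurations); its error is a
  few percent of the cell probability in deep tails.
- emcee ensembles: differential-evolution + snooker moves, half the chain
  discarded as burn-in, split-R-hat recorded per fit.  Default chain
  lengths (900 steps for correlation fits, 1500 for the trend, 450 per
  model for the comparison) were sized so a full test run of the package
  completes in minutes on one CPU; they can be raised via keyword
  arguments for publication-grade fits.
- Ties in the discrete optima resolve deterministically: the smallest
  candidate position on sliders, the target-richer option at an exact
  binary threshold, the midpoint on an indifferent linear item, the
  smallest donation at a utility tie.
- SVO angles use the plain arctangent of (w̄_t − 50)/(w̄_s − 50) in
  degrees, range (−90°, 90°), no quadrant unwrapping; item thresholds are
  always computed from item endpoints, never hard-coded.

## Known limitations

- The anchor-policy generator derives each respondent's anchor from the
  base slider's mapping of her λ; other anchoring schemes (e.g. verbal
  category midpoints) would change the anchor-account predictions only by
  a reparameterization of the mean, not the comparison logic.
- The censored-MVN correlation prior is uniform over correlation
  matrices; with very small samples the posterior median of a correlation
  is pulled slightly toward zero.
- The hierarchical fit assumes κ constant across targets and sliders for
  a participant, as the identification strategy requires.
- `fit_distance_trend` models a single monotone population trend with
  participant intercepts; it does not include participant-specific slopes.
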