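# lambdaslider

Design, simulation and Bayesian estimation for welfare-tradeoff slider
instruments.

## The problem

How much of her own payoff is a person willing to give up to raise (or
lower) someone else's payoff?  The standard formalization writes a decision
maker's utility for an allocation (w_s to self, w_t to the target) as

    u = w_s + λ w_t

where λ is the **welfare tradeoff ratio** toward that target: λ ≈ 1 means
the target's payoff counts like one's own, λ < 0 means paying to harm.
Classic instruments (binary allocation tasks, triple-dominance items, the
six-item SVO slider measure) recover λ only up to a small set of switch
thresholds, forcing a trade-off between precision and the number of
responses collected.

A **quadratic slider** removes that trade-off by mechanism design.  With
payoff functions

    w_s(x) = −a x² + b_s ,   w_t(x) = 2 a x + b_t ,   x ∈ [x_min, x_max],

the utility −a(x − λ)² + const peaks exactly at x = λ: a utility-maximizing
respondent's slider position *is* her welfare tradeoff ratio, so one
response yields a continuous λ estimate.  Adding an inequity-aversion term,

    u = w_s + λ w_t − κ |w_s − w_t| ,   κ ∈ [0, 1),

the optimum becomes piecewise, (λ+κ)/(1−κ) where w_s ≥ w_t and
(λ−κ)/(1+κ) where w_s < w_t, so responses on sliders with opposite payoff
offsets identify λ and κ jointly.

The package is for quantitative researchers in social decision making who
want to design such sliders, simulate respondents, and fit the associated
measurement models without collecting data first.  It covers:

- **slider_design** — constructing/validating quadratic sliders, payoff
  ranges, equal-payoff points, raw-position (χ ∈ [0,1]) ↔ λ-scale mappings;
- **respondent** — exact optima under the (in)equity-averse utility and two
  stochastic response policies (utility-based vs raw-position anchoring);
- **estimation** — identity readout, the closed-form two-slider (λ, κ)
  inversion, reliability odds-scaling ρ′ = nρ/(1+(n−1)ρ), Bayesian
  censored-multivariate-normal correlation fits, hierarchical λ/κ
  estimation, and a monotone social-distance trend model;
- **alt_measures** — binary-task thresholds, dominance-task validity, SVO
  angle scoring and its theoretical step function of λ;
- **model_compare** — cross-slider predictions and a bridge-sampled log
  Bayes factor between utility-based and anchor-based responding;
- **synthetic_data** — seeded panels with the structure of the three
  validation studies, plus a dictator-style donation decision;
- a `lambda-slider` command-line interface over all of the above.

## Worked example

```python
import numpy as np
from lambdaslider import (
    Preference, NoiseModel, load_slider_fixtures, optimal_position,
    equal_payoff_point, reliability_of_average, point_estimate_lambda_kappa,
)

sliders = load_slider_fixtures()
std = sliders["standard"]          # a=11.25, bs=70, bt=50, x in [-2, 2]

print(equal_payoff_point(std))     # 0.6666666666666667
print(optimal_position(std, Preference(lam=1.0)).x)        # 1.0
print(optimal_position(std, Preference(lam=3.0)).x)        # 2.0  (clipped)

# inequity aversion biases the response toward the equal split
print(optimal_position(sliders["balanced"], Preference(0.3, 0.5)).x)
# 0.7728105208558367  (the equal-payoff point of that slider)

# invert two offset-slider responses back to (lam, kappa)
est = point_estimate_lambda_kappa(x1=1.0, x2=0.2)
print(est.lam, est.kappa)          # 0.5 0.25

# averaging 3 responses at single-response reliability 0.858
print(round(reliability_of_average(0.858, 3), 3))          # 0.948
```

The first numbers say the reference slider equalizes payoffs at x = 2/3 and
returns λ itself for interior preferences while clipping λ = 3 to the range
bound.  The inversion recovers λ = 0.5 and κ = 0.25 from positions 1.0 and
0.2 on the self-favoring and target-favoring sliders, and the reliability
algebra shows three averaged slider responses reach a reliability of 0.948.

A full simulate-then-estimate loop from the shell:

```bash
lambda-slider simulate --preset inequity --seed 1 --out scratch/panel
lambda-slider estimate --responses scratch/panel/responses.csv \
    --method hierarchical --out scratch/fit.json
lambda-slider reliability --rho 0.858 --n 3     # prints 0.947717
```

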