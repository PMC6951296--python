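# tskallometry

Takagi–Sugeno–Kang (TSK) fuzzy models for bivariate allometric analysis:
polyphasic loglinear allometry in log–log ("geometrical") space, its
complex-allometry counterpart in the original ("arithmetical") scales,
and the machinery connecting the two — subtractive-clustering rule
induction, breakpoint detection by firing-strength intersection, and
retransformation bias correction.

## The problem

Classical allometry relates a trait *y* to a size covariate *x* through
Huxley's power law *y* = *βx*<sup>*α*</sup>, usually fitted as a straight
line in (*u*, *v*) = (ln *x*, ln *y*). Many real datasets bend in
log–log space: the allometric exponent changes between growth phases
(small vs large leaves, juveniles vs adults), with one or more
breakpoints separating the phases. Broken-line regression handles this
but needs starting values and fights local maxima. A first-order TSK
fuzzy model instead blends *q* local lines with smooth, normalized
Gaussian weights ("firing strengths"):

    v_TSK(u) = Σᵢ ϑⁱ(u) · (ln βᵢ + αᵢ u),      ϑⁱ(u) = μᵢ(u) / Σₖ μₖ(u)

with μₖ(u) = exp(−½((u−θₖ)/λₖ)²). The number of rules *q* and the
centers θₖ come from subtractive clustering of the data (the cluster
radius *r_a* is the single tuning knob), the consequent coefficients
from least squares or Gaussian maximum likelihood, and each breakpoint
is simply the point where two adjacent firing strengths cross — no
starting values, no profile likelihood. Back-transforming gives a
generalized power law *y* = *β*(x)·x^*α*(x)·δ with covariate-dependent
parameters, where δ corrects the retransformation bias E[e^ε] ≠ 1
(lognormal, Duan smearing, or a moment-series estimate with its order
chosen by maximizing Lin's concordance). For two-rule models the sign
of ψ = (λ₂²−λ₁²)/(2(λ₁λ₂)²) decides which phase dominates as x → ∞,
where the mean response approaches a pure Huxley power law.

The package is for ecologists and biostatisticians analysing paired
positive trait data (leaf area–biomass, body mass–organ mass,
length–weight) who want phase structure, breakpoints and bias-corrected
arithmetic-scale predictions from a single coherent fit.

## Worked example

```python
import tskallometry as tk

# Biphasic synthetic data: two size cohorts, exponents 0.9 and 1.2,
# phase transition at u = ln x = 4.0, log-scale noise sd 0.3.
spec = tk.GeneratorSpec(n=5000, seed=1, u_dist="cohorts")
ds, truth = tk.generate(spec)

report = tk.fit_tsk_at_q(ds, target_q=2)   # radius search -> 2 rules
print("q          =", report.q)
print("slopes     =", report.model.consequents.slope.round(4))
print("breakpoint =", report.breakpoints.points.round(4))
print("CCC        =", round(report.metrics.ccc, 4))
```

prints

```
q          = 2
slopes     = [0.9023 1.1898]
breakpoint = [4.0186]
CCC        = 0.9935
```

The fitted phase exponents recover the generating values (0.9, 1.2)
within about 1%, the breakpoint lands within 0.02 log units of the true
phase transition at 4.0, and Lin's concordance of 0.9935 rates the
geometric-space fit "excellent". Continuing,

```python
_, cf = tk.select_cf_order(report.residuals, ds.y,
                           report.model.predict(ds.u))
y_hat = tk.mean_response_arithmetic(report.model, cf, ds.x)
print("delta      =", round(cf.value, 4))        # 1.0454 ~ e^(0.3^2/2)
print("alpha_inf  =", round(tk.asymptotic_power_law(report.model, cf).alpha_inf, 4))
```

the series correction factor δ = 1.0454 matches the lognormal value
e^{σ²/2} = 1.046 for the simulated noise, and the asymptotic exponent
1.1898 is the large-phase slope: at large x the blended model behaves as
a simple power law of the dominant phase.

The same pipeline is available from the shell:

```bash
tskallometry simulate --seed 1 --out data.csv
tskallometry fit --input data.csv --space pla --radii 0.34 --out model.json
tskallometry breakpoints --model model.json
tskallometry retransform --model model.json --input data.csv --cf series:auto --out pred.tsv
```

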