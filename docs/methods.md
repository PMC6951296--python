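# Methods

## Model

A response *y* and covariate *x* are positive traits with *y* → 0 as
*x* → 0 (zero-intercept allometry). Under multiplicative error the
analysis moves to geometrical space, (*u*, *v*) = (ln *x*, ln *y*),
where the mean response is modeled as the general output of a
first-order TSK fuzzy system:

    v_TSK(u) = Σᵢ₌₁..q ϑⁱ(u) fⁱ(u),    fⁱ(u) = ln βᵢ + αᵢ u

The firing strengths ϑⁱ(u) = μᵢ(u)/Σₖ μₖ(u) are normalized Gaussian
memberships μₖ(u) = exp(−½((u−θₖ)/λₖ)²). Each rule is one loglinear
allometric phase with exponent αᵢ; the blend is a polyphasic loglinear
model that degenerates exactly to ordinary log–log regression when
q = 1 (ϑ¹ ≡ 1). Substituting the consequents and rearranging shows the
blend is also a loglinear law with covariate-dependent parameters,
v = ln β(u) + α(u)·u with α(u) = Σ ϑⁱ(u)αᵢ and ln β(u) = Σ ϑⁱ(u)ln βᵢ —
i.e., back-transformation yields a multiple-parameter complex allometry
(MPCA) form y = β(x)·x^α(x)·δ in the original scales.

The arithmetic-space variant fits the same blended structure directly to
(x, y) with linear consequents fⁱ(x) = c_{i1} + c_{i2}x and composite
log-normal memberships μᵢ(x) = (e^{hᵢ(x)} − 1)/(e − 1),
hᵢ(x) = exp(−½((ln x − θᵢ)/λᵢ)²). The composition keeps the degree in
[0, 1], peaks at ln x = θᵢ and vanishes as x → 0⁺, respecting the
zero-intercept constraint. (The normalization constant must be
(e − 1)⁻¹; the sign-flipped variant would produce negative degrees.)

### Breakpoints

A phase-transition point is where two adjacent firing strengths cross.
The detector scans 10,001 grid points over the data range for changes
of the dominant (argmax) rule and refines each crossing by bisection to
1e−10; Gaussian firing strengths are smooth, so this grid cannot skip a
realistic crossing. For q = 2 the crossing has a closed form: the log
membership ratio is τ(u) = ψ·φ(u) + ξ with

    ψ = (λ₂² − λ₁²) / (2(λ₁λ₂)²),   φ(u) = (u + (λ₂²θ₁ − λ₁²θ₂)/(λ₁² − λ₂²))² ≥ 0

and ξ constant, so crossings are roots of a quadratic; the
implementation computes both routes and asserts agreement to 1e−8.
Equal widths are the degenerate case (τ affine in u, single crossing at
the center midpoint). The criterion is deliberately non-statistical: no
confidence interval is attached. When no crossing falls inside the data
range the model is effectively single-phase there — a valid outcome,
not an error.

### Asymptotics

For q = 2, the sign of ψ decides the limit: ψ > 0 sends τ → +∞, so the
second (wider) rule dominates and E(y|x) → β₂x^{α₂}δ as x → ∞; ψ < 0
hands the limit to rule 1. With equal widths the dominant rule follows
from the sign of τ's slope, (θ₂−θ₁)/λ²; when centers also coincide the
memberships are identical and the limit is the half-half blend. The
correction factor is absorbed into the asymptotic normalization
constant.

### Retransformation bias

exp(E[v|u]) underestimates E[y|x] because E[e^ε] ≠ 1. Four correction
factors δ are provided: lognormal e^{σ²/2} (exact under Gaussian
errors), Duan's smearing mean(e^{resid}) (nonparametric, can
overcompensate under heavy tails), the two-moment truncation 1 + σ²/2,
and the n-term moment series Σ_{k≤n} m_k/k! with empirical raw moments
m_k. The series order is selected by maximizing Lin's concordance
between observations and the corrected mean response over n = 0..10
(ties to the smallest n); the cap limits moment-estimation noise, which
grows quickly with order. Raw (not central) moments are used, matching
the series for E[e^ε] directly; for least-squares residuals m₁ ≈ 0 so
the distinction is immaterial.

## Estimation

**Rule induction.** Subtractive clustering on the joint
(input, output) pairs — (u, v) for the geometric model, (x, y) for the
arithmetic one — with min–max normalization per dimension. Potentials
use the kernel exp(−(4/r_a²)·d²); after each center is selected its
potential is subtracted with the wider kernel r_b = 1.25·r_a; candidates
between the accept (0.5) and reject (0.15) fractions of the first
potential are resolved by the standard distance rule
(d_min/r_a + P/P₁ ≥ 1). Ties in maximal potential break to the lowest
index, making the procedure deterministic. Only the input coordinate of
each center becomes a membership center; for the arithmetic family the
center's x-coordinate is mapped through ln (the membership core operates
on ln x). Widths come from the radius: λ = r_a·range/√8 (in ln-x range
units for the arithmetic family), the convention under which a cluster
of radius r_a matches the Gaussian whose exponent equals the potential
kernel's. The cluster radius r_a is the analysis knob: the `sweep`
command (or `fit_tsk_at_q`) automates the exploration of r_a against
the induced q.

**Consequents.** The blend is linear in (ln βᵢ, αᵢ), so least squares
is a single linear solve on the design [ϑⁱ(z), ϑⁱ(z)·z]. A recursive
(one-observation-at-a-time) variant is provided for parity with
sequential identification schemes; its contract is convergence to the
batch normal-equations solution. A rule that fires nowhere on the data
makes the design rank-deficient and raises an error naming the rule.

**Maximum likelihood.** Gaussian errors with either a constant scale σ
(homoscedastic) or the log-linear scale sd(u) = ln(σ + k·u) with
σ + k·u > 1 enforced over the data hull (heteroscedastic). For fixed
variance parameters the likelihood is maximized in the consequents by
weighted least squares, so the variance parameters are profiled — a
closed form for the homoscedastic case, a 2-D Nelder–Mead search for
(σ, k) warm-started at the homoscedastic optimum (σ = e^{sd}, k = 0).
Profiling is exact joint estimation here, not a two-stage
approximation. Because the homoscedastic scale is nested in the
log-linear family at k = 0, the heteroscedastic negative log-likelihood
never exceeds the homoscedastic one. Reported log-likelihoods include
all constants (½ln 2π terms); AIC = 2p − 2logL with p = 2q + 1 or
2q + 2. Wald intervals for (σ, k) come from a finite-difference Hessian
of the profile likelihood; the interval for k excluding zero is the
model-based heteroscedasticity check.

**Diagnostics.** Lin's concordance (population moments) with the
conventional agreement classes (poor < 0.90 ≤ moderate < 0.95 ≤ good
< 0.99 ≤ excellent); R², SEE = √(SSE/(n−p)); MPE and MPSE as signed and
absolute mean percent errors (denominator selectable between predicted
and observed, both conventions circulate in the forestry literature);
Breusch–Pagan via the auxiliary regression of squared residuals on the
covariate, reported in the studentized n·R² form by default with the
original χ² scaling behind a flag. Normality diagnostics are delegated
to standard library routines rather than reimplemented.

## Synthetic data

The generator draws u, evaluates the blended truth v_TSK(u), adds
Gaussian noise in geometric space (multiplicative in arithmetic space)
with constant or log-linear scale, and returns (x, y) = (e^u, e^v).
Defaults define the package's reference study conditions: two phases
with exponents (0.9, 1.2), centers (1.8, 6.2), equal widths 1.35,
intercepts crossing at u = 4.0 (which is also the firing-strength
crossing), noise sd 0.3, n = 5,000. Three u-sampling modes:

* `uniform` (default) — uniform over (0, 8);
* `lognormal` — Gaussian in u, mimicking size-frequency skew;
* `cohorts` — an equal mixture of Gaussian size cohorts centered at
  the phase centers (sd 1.15), the way biphasic samples arise in the
  field (e.g., juvenile and adult cohorts).

What the generator does *not* emulate: measurement error in x,
non-Gaussian error tails, within-phase curvature, and sampling designs
correlated with the residuals. Passing recovery tests therefore show
the estimator chain is consistent under its own assumptions, not that
any particular field dataset satisfies them.

### Design of the recovery study

The 50-replicate study refits each simulated dataset end to end
(radius selection to q = 2, clustering, width mapping, least squares,
breakpoint detection) and requires phase exponents within 2% and the
breakpoint within 0.1 log units, in at least 90% of replicates. Three
design constraints shape the reference conditions, all fixed a priori
from how the method works:

1. *Density structure must align with phases.* Subtractive clustering
   is a density method; on uniformly sampled u there is no density
   signal at the phase boundary, the induced centers track arc-length
   density instead of phases, and the crossing of the induced firing
   strengths is displaced by 1–2 log units regardless of sample size.
   The study therefore uses the cohort sampling mode, under which the
   potential maxima sit at the phase centers.
2. *Truth widths match the width convention.* The refit assigns
   λ = r_a·range/√8; setting the generating widths to the value this
   map produces at the radii the search selects (≈1.35 here) makes the
   recovery well-specified. A deliberate mismatch instead measures
   robustness to misspecification, which is a different (and worthwhile)
   experiment.
3. *Tolerances must be multiples of the sampling error.* With noise
   sd 0.3 and ≈2,500 observations per phase, the within-phase slope
   standard error is ≈ 0.3/(sd(u)·50); a 2% relative tolerance on
   exponents 0.9/1.2 is ≥ 2.4 standard errors only when the
   within-phase spread sd(u) is ≈ 1.15, which fixes the cohort sd and,
   with the separation (1.8 vs 6.2), the overlap between phases.

At these conditions the study passes 48–49 of 50 replicates, with mean
absolute breakpoint error ≈ 0.05 log units.

The arithmetic-space demonstration uses a narrower dynamic range (about
two decades in x): min–max normalization in raw scales compresses
heavily skewed data onto the origin, and density clustering in
arithmetic space is only informative when the data do not span many
decades — which matches how and when direct-scale analyses are used in
practice.

## Numerical choices

* Natural logarithms everywhere; no base-10 option in core math.
* Firing strengths are computed in the log domain (softmax) for the
  Gaussian family, so points far from all centers stay finite; the
  composite family falls back to the same limit when every degree
  underflows (expm1(h) ~ h).
* Membership centers are stored sorted ascending, with consequents
  permuted consistently; breakpoints are invariant under relabeling.
* Bisection tolerance 1e−10 on breakpoints; LS via `numpy.linalg.lstsq`
  (SVD); Nelder–Mead with xatol 1e−8 for the 2-D variance profile, a
  large-value penalty keeping σ + k·u above 1.
* Rows with non-positive or missing x or y are dropped with a logged
  count (strict mode raises); fully invalid files raise.
* Degenerate inputs: all-identical cluster points give q = 1; constant
  covariate raises in regression and in Breusch–Pagan.

## Limitations

* Breakpoint placement inherits the biases of density-based center
  selection; on data whose density ignores phase structure the
  crossing of induced firing strengths is not a consistent breakpoint
  estimator (see the recovery-study notes above).
* The asymptotic power-law analysis covers two-rule models only.
* No confidence intervals on breakpoints, by design of the criterion.
* AIC values are comparable within this implementation's likelihood
  convention, not across packages with different constant handling.
* The heteroscedastic scale ln(σ + k·u) must stay positive, so the
  admissible (σ, k) region is coupled to the covariate range
  (σ + k·u > 1 over the data hull); variance profiles that would drive
  the scale to zero inside the range sit on the constraint boundary and
  are better served by the homoscedastic model.
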