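# Methods

## Model and estimands

For a two-arm randomized trial with right-censored failure times, let
`X = min(T, C)`, `Δ = 1{T ≤ C}`, arm `Z ∈ {0, 1}` with allocation
probability `π = P(Z = 1)`, and baseline covariates `V`. The restricted
mean survival time (RMST) of arm `z` over a prespecified horizon `τ` is

    θ_z = E{min(T, τ) | Z = z} = ∫₀^τ S_z(t) dt,

the area under the survival curve up to `τ`. The treatment contrast is
`θ = θ₁ − θ₀`, estimated by the difference of the areas under the
arm-wise Kaplan–Meier curves. The package assumes randomization
(`V ⊥ Z`), conditionally independent censoring (`C ⊥ T | Z`), and — for
all power calculations — a common censoring law (`C ⊥ Z`).

### Variance estimators

Two consistent estimators of `Var{√n(θ̂ − θ)}` are computed:

* **plug-in**: `σ̂₁² = Σ_z ∫₀^τ {∫_t^τ Ŝ_z du}² / Ȳ_z(t) dΛ̂_z(t)`,
  an exact sum over the arm's event times in `[0, τ]`, where `Ȳ_z` is the
  at-risk fraction normalized by the *total* sample size and `Λ̂_z` the
  Nelson–Aalen estimate;
* **score (residual) form**: `σ̂₂² = n⁻¹ Σ H_i²` with per-subject
  influence scores

      H_i = −Z_i ∫₀^τ {∫_t^τ Ŝ₁ du / Ȳ₁(t)} dM̂₁,ᵢ(t)
            + (1 − Z_i) ∫₀^τ {∫_t^τ Ŝ₀ du / Ȳ₀(t)} dM̂₀,ᵢ(t),

  where `M̂_{z,i}` are the counting-process martingale residuals.

The Wald test defaults to `σ̂₂²` so that the standard and augmented tests
differ only by the augmentation term; `σ̂₁²` is always reported for
cross-checking. The two agree asymptotically (and within 5% at n = 10⁴
in the test suite) but differ in finite samples — the plug-in form uses
`Y²` denominators, not the Greenwood-style `Y(Y − d)`.

### Covariate augmentation

The augmented estimator subtracts a mean-zero term,
`θ̂_aug = θ̂ − n⁻¹ Σ (Z_i − π) ĉᵀV_i`, with

    ĉ = {π(1−π) Σ V_i V_iᵀ}⁻¹ Σ (Z_i − π) V_i H_i,

the projection of the influence scores onto the span of `(Z − π)V`. At
`π = 1/2`, `(Z_i − π)² ≡ 1/4`, so ĉ is the exact least-squares minimizer
and `σ̂_aug² = n⁻¹ Σ {H_i − (Z_i − π) ĉᵀV_i}² ≤ σ̂₂²` holds for every
dataset, not just asymptotically. Randomization makes the augmentation
mean-zero for any fixed (or convergent) coefficient, so the estimator
stays consistent regardless of how well the covariates explain the
outcome. Covariates enter raw; a `standardize` flag rescales columns
(scale-only — a shift would break the exact mean-zero structure in
finite samples) for conditioning and cannot change `θ̂_aug`, which is
invariant under any invertible linear reparameterization of `V`.
Collinear covariate matrices are a hard error by default (condition
number above 1e10); an explicit `allow_pinv=True` switches to a
pseudo-inverse.

## Local power

Under a local (1/√n) alternative and a common censoring survival `G`,

    σ̃₁² = {π(1−π)}⁻¹ ∫₀^τ {∫_t^τ S₀ du}² / {S₀(t) G(t)} dΛ₀(t)

depends only on the control survival curve and the censoring law. The
augmentation removes `Q₂ = π(1−π) e²`, where `e²` is the variance
explained by projecting the (null) martingale-residual integrals onto
the covariates. Two-sided power at an RMST-difference alternative
`θ_alt` is

    Φ(z_{α/2} − θ_alt/v) + 1 − Φ(z_{1−α/2} − θ_alt/v),

with `v² = σ̃₁²/n` (standard) or `(σ̃₁² − π(1−π)e²)/n` (augmented);
`z_{α/2}` is the lower-tail quantile. The augmented formula is derived
at `π = 1/2` and the implementation refuses other allocations for it
(the estimator itself accepts general `π`).

### Estimating the design inputs

From control-only reference data (or a blinded pooled snapshot), with
single-group scores `g_i = ∫₀^τ {∫_t^τ Ŝ₀ du / Ȳ₀(t)} dM̂₀,ᵢ(t)`:

* `σ̃₁²` — **score form** (default): `n⁻¹ Σ g_i² / {π(1−π)}`, the
  single-group analogue of `σ̂₂²`; or the **plug-in form**: the integral
  above with Kaplan–Meier `S₀`, reverse Kaplan–Meier `G` (left limits at
  the event times) and Nelson–Aalen increments. The score form is the
  default because it is the natural companion of the score-form test
  variance; the plug-in form is used whenever a parametric censoring law
  is supplied instead of being estimated.
* `ê² = aᵀB⁻¹a / {n⁺ π²(1−π)²}` with `a = Σ g_i V_i`, `B = Σ V_i V_iᵀ`.
  The `{π(1−π)}⁻²` factor converts the single-group score scale to the
  trial-level influence scale (trial scores carry `1/π_z` through the
  arm-wise at-risk fractions), so that `π(1−π)ê²` consistently estimates
  the variance actually removed by augmentation. The test suite checks
  this identity directly against `σ̂₂² − σ̂_aug²` on large simulated
  trials. For a constant covariate `ê² = 0` exactly, because martingale
  residuals sum to zero at every event time.

Parametric specifications (exponential, piecewise exponential, uniform
censoring) evaluate `σ̃₁²` by adaptive quadrature (relative tolerance
1e−8, integration split at hazard change points); all Kaplan–Meier-based
integrals are exact step sums, never quadrature.

### Sample size and covariate selection

`required_n` returns the smallest `n` on the grid
`{n_min, n_min + step, …}` (default step 10) whose predicted power
reaches the target, erroring with the attained power if the grid is
exhausted. `stepwise_select` runs greedy forward selection by gain in
`ê²`, returning the full path; adding a covariate can never decrease
`ê²` (nested quadratic forms), so the caller decides where the gain
saturates — typically by looking at the per-stage predicted power the
CLI reports alongside.

## Blinded sample-size re-estimation

At a blinded review with `n_mid` subjects followed to `τ`, the pooled
sample (treatment labels never read — passing data with an arm column is
an error unless explicitly stripped) yields pooled Kaplan–Meier /
reverse Kaplan–Meier curves and a pooled `ê²` under the pooled (null)
Nelson–Aalen fit. Because the local power formula is free of the
treatment assignment, this estimates the power of the eventual test
without unblinding; the re-estimation scans `n = n_mid, n_mid + step, …`
and adopts the first `n` reaching the target, never shrinking below the
subjects already observed. In the replication harness the final analysis
reuses the first `n_final` subjects of the same deterministic subject
stream, extended past `n_mid` under the same random state — an
assumption about accrual between review and final analysis, since
nothing in the blinded procedure pins it down.

## Synthetic-data generator

The generator emulates a 1:1 randomized trial with τ = 5 (years),
control failure times exponential with `λ₀ = −ln(0.2)/5` (five-year
survival 0.2), and Uniform(0, 8) administrative censoring, in six
scenarios: null (family 1), proportional hazards with hazard ratio 0.7
(family 2, true RMST difference 0.5142), and a non-proportional-hazards
family 3 whose treatment hazard is `λ₀` before `t = 1` and a rate `λ₂`
afterwards, solved by bracketed root finding (plug-back accurate to
1e−10) to match the family-2 difference. Covariates `V₁ = b₁ + ε₁`,
`V₂ = b₂ + ε₂` are N(0, 2); the failure-time driver is
`U = Φ₃(b₁ + b₂ + ε)` (setting "a": prognostic covariates, latent
correlation 1/√6 with each Vⱼ) or `U = Φ₁(ε)` (setting "b": pure noise),
and `T` is the arm's inverse CDF applied to `−log U`. Reference data
are control-law draws; the "mis-matched" variant keeps only subjects
with `V₁ < 1` and `V₂ < 1`, emulating a reference population with a
distorted covariate distribution.

What the generator does *not* emulate: staggered entry and
calendar-time accrual, covariate-dependent censoring, ties (all times
are continuous), categorical covariates, and non-copula forms of
covariate–outcome dependence. Passing tests therefore demonstrate
correctness of the estimators and calibration of the design machinery
under these idealized conditions, not robustness to, e.g., informative
censoring (which the method itself excludes by assumption).

Randomness is counter-based: every replicate draws from
`default_rng([master_seed, stream, replicate])`, so results are
deterministic, order-independent, and parallelizable.

## Numerical choices and degenerate inputs

* Ties (if present in user data): events at `t` count against the
  at-risk set `{X ≥ t}` including subjects censored at `t`; the reverse
  Kaplan–Meier risk set for censorings excludes same-time events.
* Follow-up shorter than `τ`: the Kaplan–Meier curve is extended flat
  with a warning (`extend="strict"` errors instead). The simulated
  designs guarantee support (`C ~ U(0, 8)`, `τ = 5`); real data may not.
* No events in `[0, τ]`: variances degenerate to 0 with a warning; the
  Wald test refuses to run.
* `π(1−π)e² ≥ σ̃₁²` in the power formula is an error, never silently
  clipped.
* Condition-number ceiling 1e10 for covariate Gram matrices.

## Replication sizes used by the checks

The packaged acceptance script uses 10,000 replicates for the fixed-n
rejection rates, 2,000 reference sets for the mean design-stage
predicted power, and 1,000 replicates of the blinded re-estimation loop;
the test suite uses 3,000 / 1,000 / 1,000 with binomial 3-SE tolerance
bands at those counts. Monte-Carlo calibration tests (variance
estimators versus the empirical variance of `θ̂`) use 400–2,000
replicates at n = 500–2,000 with a 10% relative band.

## Known limitations

* No left truncation, interval censoring, or competing risks; no
  stratified or weighted comparisons.
* The augmented power machinery requires equal allocation.
* The local-power approximation degrades for large effects (where the
  required `n` is small anyway); the blinded re-estimation is intended
  for moderate-to-large trials.
* The truncation time `τ` must be prespecified; data-dependent `τ` is
  out of scope.
* Group-sequential or unblinded interim adaptations are out of scope.
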