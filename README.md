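# rmstaug

Restricted-mean-survival-time (RMST) tests for two-arm randomized
trials, with covariate augmentation, a local-power formula for design,
and blinded mid-trial sample-size re-estimation.

The RMST over a prespecified horizon τ, `θ_z = ∫₀^τ S_z(t) dt`, is the
area under the survival curve — a model-free treatment-effect measure
that stays interpretable when proportional hazards fails (late-onset
effects of immunotherapies being the canonical example). This package
is for trial statisticians who want to

* **test** `θ = θ₁ − θ₀` with a Wald statistic built from arm-wise
  Kaplan–Meier areas and martingale-residual variance estimates;
* **gain power for free** by augmenting the estimator with baseline
  covariates, `θ̂_aug = θ̂ − n⁻¹ Σ (Z_i − π) ĉᵀV_i`, where ĉ projects the
  per-subject influence scores onto `(Z − π)V` — unbiased under
  randomization, never larger in estimated variance at 1:1 allocation;
* **size a trial** from control-only reference data via the local-power
  approximation `σ̃₁² = {π(1−π)}⁻¹ ∫₀^τ {∫_t^τ S₀}²/(S₀G) dΛ₀`, which
  needs only the control survival curve, the censoring law, and (for
  the augmented test) the covariate-explained variance `e²`;
* **re-estimate the sample size mid-trial** from pooled, treatment-
  blinded data, preserving trial integrity and the type-I error.

A simulation engine reproduces the operating characteristics of the
whole pipeline (six scenarios: null / proportional-hazards /
non-proportional-hazards × prognostic / noise covariates, Gaussian-
copula covariate dependence, uniform administrative censoring).

See `docs/methods.md` for the estimators, formulas and numerical
conventions.

## Worked example

Analyze a simulated trial (proportional-hazards scenario, true RMST
difference 0.514 over τ = 5), then design and blindly re-size a new one:

```python
import rmstaug as ra
from rmstaug.power import DesignSpec, reference_design_inputs, required_n

ds = ra.generate_trial("2a", 500, seed=7)
std = ra.standard_test(ds, tau=5.0)
aug = ra.augmented_test(ds, tau=5.0)
print(f"standard : diff={std.theta_diff:.3f}  se={std.se:.3f}  p={std.p_value:.4f}")
print(f"augmented: diff={aug.theta_aug:.3f}  se={aug.se:.3f}  p={aug.p_value:.4f}")

ref = ra.generate_reference("2a", 200, seed=1)          # control-only reference
inputs = reference_design_inputs(ref, tau=5.0)
design = DesignSpec(tau=5.0, theta_alt=0.514, target_power=0.8)
print("n standard :", required_n(design, inputs["sigma_tilde_sq"]))
print("n augmented:", required_n(design, inputs["sigma_tilde_sq"],
                                 inputs["e_sq"], augmented=True))

pooled = ra.generate_trial("2a", 200, seed=2).blinded() # mid-trial snapshot
review = ra.reestimate_n(pooled, design, use_augmentation=True)
print(f"blinded review: n_mid={review.n_mid} -> n_final={review.n_final}")
```

prints

```
standard : diff=0.637  se=0.173  p=0.0002
augmented: diff=0.536  se=0.158  p=0.0007
n standard : 420
n augmented: 350
blinded review: n_mid=200 -> n_final=340
```

The augmented estimate is closer to the truth with a smaller standard
error; augmentation cuts the design-stage sample size from 420 to 350,
and the blinded review of a fresh trial lands at 340. Estimates are also
available as sklearn-style estimators (`RMSTDifference`,
`AugmentedRMSTDifference` with `.fit()` and fitted `_` attributes).

The same operations are exposed on the command line for CSV/TSV data
with columns `time`, `event`, `arm`, `cov_*`:

```bash
rmstaug simulate --scenario 2a --n 500 --seed 7 -o trial.csv
rmstaug augtest trial.csv --tau 5
rmstaug samplesize --reference ref.csv --tau 5 --theta-alt 0.514 --augmented
rmstaug reestimate --nmid-file blinded.csv --config design.yaml --augmented
rmstaug select-covariates ref.csv --tau 5 --n 500 --theta-alt 0.514
rmstaug run-study --config study.yaml -o tables/
```

All results are JSON (single analyses) or TSV (study tables) and embed
the resolved parameters and seed.

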