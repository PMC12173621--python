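# delimech

Biaxial mechanics and sensory texture analysis of deli meats: from raw
planar-biaxial force–displacement recordings to incompressible hyperelastic
material models, sparse automated model discovery, and the statistics that
link physical stiffness to perceived texture.

## Who this is for

Food- and soft-tissue-mechanics researchers characterising thin sheet-like
products (deli slices, membranes, films) with a planar biaxial tester, and
sensory scientists relating those measurements to Likert texture panels.
The package covers four plant-based and four animal deli meat products end
to end and ships their mean stress–stretch dataset (five loading modes ×
two directions × eleven points per product, n = 8 samples each).

## The models

A thin square sample is stretched along two orthogonal axes
(λ₁, λ₂); incompressibility fixes the thickness stretch λ₃ = 1/(λ₁λ₂).
With gauge lengths L₁, L₂ (mm), thickness t (mm) and forces F₁, F₂ (mN),

    λ₁ = l₁/L₁,  λ₂ = l₂/L₂,  P₁₁ = F₁/(L₂ t),  P₂₂ = F₂/(L₁ t)   [kPa]

For an isotropic strain energy ψ(I₁, I₂) the zero-thickness-stress
condition gives the biaxial Piola stresses

    P₁₁ = 2(λ₁ − λ₁⁻³λ₂⁻²) ∂ψ/∂I₁ + 2(λ₁λ₂² − λ₁⁻³) ∂ψ/∂I₂

(and symmetrically for P₂₂). Three model families implement ψ:

- **neo-Hooke** ψ = c₁/2 (I₁ − 3), shear modulus μ = c₁;
- **Mooney–Rivlin** ψ = c₁/2 (I₁ − 3) + c₂/2 (I₂ − 3), μ = c₁ + c₂;
- an **eight-term discovery network**: identity and exponential of the
  first and second powers of (I₁ − 3) and (I₂ − 3), with non-negative
  external (kPa) and internal (dimensionless) weights, trained by Adam on
  all five loading modes simultaneously with an L1 penalty that prunes the
  library down to an interpretable two-term model.

The classical fits are ordinary linear least squares; E = 3μ under
incompressibility (ν = ½). Goodness of fit is the per-curve coefficient of
determination averaged over the retained mode–direction curves (hold
channels of the strip modes excluded).

The sensory side scores the 10-item/7-point food-neophobia and
16-item/5-point meat-attachment questionnaires, summarises a
twelve-feature 5-point texture panel, runs per-feature one-way ANOVA over
products, and correlates product stiffness with feature means by Spearman
rank, with an exact full-permutation p-value at n ≤ 10.

## Worked example

```python
import numpy as np
import delimech as dm

ref = dm.load_reference_dataset()            # 8 products, 5 modes, 11 points

fit = dm.fit_model(ref["PT"], "neo_hooke")   # plant turkey
print(f"mu = {fit.moduli.shear_mu:.1f} kPa, E = {fit.moduli.elastic_E:.1f} kPa")
print(f"R2 = {fit.r2_mean:.2f} +/- {fit.r2_std:.2f}")

res = dm.discover_two_term(ref["PT"], dm.TrainingConfig(seed=0))
print(res.term_labels, f"R2 = {res.r2_mean:.2f}")
```

prints

```
mu = 127.2 kPa, E = 381.5 kPa
R2 = 0.82 +/- 0.14
('(I1-3)', 'exp(I1-3)-1') R2 = 0.82
```

i.e. plant turkey has a shear modulus of about 127 kPa (an elastic modulus
of about 380 kPa — roughly three times stiffer than its animal
counterpart), and the sparse discovery selects a linear plus exponential
first-invariant energy as its best two-term model.

The same estimators are available in scikit-learn form
(`NeoHooke`, `MooneyRivlin`, `ConstitutiveNetwork`, `TwoTermDiscovery`:
`fit(X, y)` on (n, 2) stretch pairs and stress pairs in kPa, fitted
attributes `c1_`, `w_ext_`, …, and `predict` returning stresses), and a
CLI (`delimech convert | fit | discover | stats | simulate`) wraps the
library for shell use.

## Layout

- `delimech.biaxial_io` — raw recordings → stress–stretch curves, cycle
  extraction, resampling/averaging, dataset CSV I/O, packaged reference data
- `delimech.kinematics` — invariants and Piola stresses for any energy model
- `delimech.classical_fits` — neo-Hooke / Mooney–Rivlin estimators, moduli,
  goodness of fit
- `delimech.model_discovery` — the eight-term network, Adam + L1 training,
  two-term selection
- `delimech.sensory_stats` — questionnaire scoring, Likert summaries,
  ANOVA, Spearman with exact permutation null
- `delimech.synthetic_data` — generators for biaxial samples and survey
  panels with known ground truth

See `docs/methods.md` for the modelling assumptions, parameter choices and
limitations.
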