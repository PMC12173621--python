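# Methods

## Mechanical model

Deformation is homogeneous, shear-free, and perfectly incompressible:
F = diag{λ₁, λ₂, (λ₁λ₂)⁻¹}, so I₃ = 1 and the state is fully described by

    I₁ = λ₁² + λ₂² + (λ₁λ₂)⁻²,   I₂ = λ₁⁻² + λ₂⁻² + (λ₁λ₂)²,

both ≥ 3 with equality only in the reference state. Incompressibility is
enforced analytically — the pressure is eliminated through the
zero-thickness-stress condition P₃₃ = 0 — rather than penalised, which
keeps every stress evaluation exact and parameter-free. Material isotropy
is assumed throughout: the products this package targets are restructured
or extruded sheets without a single preferred fibre direction. Stretches
are guarded to [0.5, 2]; the experiments stay within [1, 1.25], and values
outside the guard indicate corrupted input rather than physics.

Energies are parameterised by (I₁, I₂) only, in kPa. `piola_biaxial`
consumes any object with `psi`, `dpsi_dI1`, `dpsi_dI2`; its correctness is
checked in the tests against central finite differences of the full
three-dimensional relation P = ∂ψ/∂F − pF⁻ᵀ, an oracle that never shares
code with the implementation.

## Raw-data processing

Reference gauge lengths are the tine spacings at the first recorded step at
which *both* axis forces reach the pre-load (30 mN by default). The
detection rule treats the axes symmetrically; the pre-load itself is a
slack-removal force, so converted curves carry a small constant stress
offset that is removed when resampled curves are re-anchored to pass
exactly through (λ, P) = (1, 0) — the convention of the packaged dataset.

Cycles are segmented on the driven gauge signal by the sign of its
increments; analysis curves come from the last (third) stretch–recovery
cycle. Loading and unloading legs of all samples are linearly interpolated
onto a common equidistant stretch grid spanning λ = 1 to the smallest
shared maximum (the tester does not always reach the prescribed
displacement; restricting to the shared support is this package's choice)
and averaged, 11 grid points by default to match the packaged data.
Linear interpolation is sufficient because recordings are dense and
monotone in stretch per leg; no smoothing is applied. For strip modes the
held channel's stress is interpolated against the *driven* stretch, so it
averages consistently and is returned with λ ≡ 1; held channels are kept
in datasets but flagged.

## Parameter identification

Both classical models are linear in their parameters, so identification is
ordinary unweighted linear least squares over all five modes stacked, both
stress components per point. Held strip-mode channels are *included* in
the fit (they are measured stresses and the loss has no exclusions) but
*excluded* from goodness of fit; both choices are arguments. No sign
constraint is placed on c₁, c₂ — fitted c₂ is genuinely negative for
several products.

Two reporting conventions coexist and are labelled wherever reported:
parameters as mean ± std of per-sample fits (`fit_samples`), and a single
fit to the mean data (`fit_model`), which is the convention the per-product
goodness-of-fit values follow. Whether per-sample fits use the 11-point
averaged curves or full-resolution curves is exposed as the grid-size
parameter rather than fixed.

**Goodness of fit.** R² defaults to the coefficient of determination
1 − SSres/SStot computed per retained mode–direction curve (eight curves:
x and y for the two off modes and equibiaxial, the stretched direction only
for the two strip modes), then mean ± std across curves. This per-curve
convention reproduces the published per-product values; a pooled
squared-Pearson-correlation variant (`method="pearson"`) is provided
because "correlation" is also a defensible reading, but it is insensitive
to affine miscalibration and systematically more lenient. Per-curve
determination values can be negative for badly fitting modes; the mean is
reported as-is. A curve with constant measured stress has no defined R²
and is dropped from the aggregates with a warning.

## Model discovery

The discovery library holds eight decoupled terms: identity and
exponential of the first and second powers of (I₁ − 3) and (I₂ − 3), with
external weights w (kPa) and internal weights w* (dimensionless), sixteen
parameters total. Term 1 alone is neo-Hooke (c₁ = 2w₁w₁*); terms {1, 5}
embed Mooney–Rivlin. The library admits C(8,2) = 28 two-term models.

Training minimises the mean squared stress error over all data points of
all five modes simultaneously (no train/test split) plus α·Σwᵢ on the
external weights, by Adam with analytic gradients. Choices, all surfaced
in `TrainingConfig`:

- **Non-negative weights**, enforced by projection after every step. The
  published discovered weights are all positive, and non-negativity keeps
  every library term convex in its invariant, hence the energy polyconvex
  on this term set.
- **L1 on external weights only** (togglable to include internal weights):
  the internal weights are dimensionless shape parameters and penalising
  them would mix scales.
- **Defaults** learning rate 10⁻³, 20 000 epochs, uniform(0, 1) seeded
  initialisation, term activity threshold 10⁻³ relative to the largest
  weight product wₖwₖ*. These are conventional Adam settings sized so that
  inactive-term weights decay below threshold within the epoch budget;
  under-training (≲5 000 epochs) is the main failure mode of sparsity
  selection, leaving spurious terms above threshold.
- **Selection**: sweep α ascending over a log grid 10⁻⁴…1 (early-stopping
  at the first success) and keep the smallest α with exactly two active
  terms; then refit those two terms with α = 0. Reported weights come from
  the refit by default, with the penalized-fit weights also recorded, since
  the provenance of published weights is not stated.

Exact published weight values are not reproducible — optimizer settings
are unstated and the weight split within a term is not identifiable from
stresses alone — so only term identity, predicted stresses and R² are
asserted.

## Sensory statistics

Questionnaire totals are simple sums after reflecting reverse-keyed items
(x → scale + 1 − x). The reverse-key sets are configuration with defaults
following the instruments' common scoring; totals are bounded by
construction to [10, 70] (neophobia) and [16, 80] (meat attachment).

Likert scores are treated as interval data: per-feature one-way ANOVA
across the eight products pools participants as independent observations
(no repeated-measures correction), significance at p < 0.05. Spearman
correlations run on product-level feature means (n = 8 points), matching
the attainable coefficient values 6/7 and 1 − 36/504; ρ is Pearson on
midranks, and for n ≤ 10 the two-sided p-value is computed by full
enumeration of all n! orderings, because the t approximation is unreliable
there. Signed ρ is always reported; no multiple-testing correction is
applied across the correlation matrix, mirroring how such panels are
conventionally reported. Stiffness defaults to the neo-Hooke elastic
modulus per product.

## Synthetic data generator

The biaxial generator emulates the study conditions: n = 8 samples per
product, five modes in the protocol order strip-y, off-y, equibiaxial,
off-x, strip-x; three triangular stretch–recovery cycles at 1 %/s to
λ = 1.10 (1.25 for prosciutto-style products); 30 mN pre-load preceded by
a 1 % slack-removal ramp whose forces reach the pre-load exactly at the
reference spacing (12 × 12 mm rakes); thickness 0.9 mm with 8 % lognormal
sample scatter. Off-mode follower stretch is √(driven stretch). Stress is
the generating model's prediction times a symmetric multiplicative
hysteresis split (loading × (1 + g), unloading × (1 − g), g = 10 % by
default, closing at the turning point) times lognormal noise with σ = 5 %.
The symmetric split makes loading/unloading averaging unbiased by
construction. Multiplicative noise is the default because stresses span an
order of magnitude across modes; an additive option exists. Forces and
gauges are back-computed through the Piola definitions so the raw pipeline
round-trips: noiselessly, the full simulate → convert → resample → fit
loop recovers generating parameters to better than 0.1 %.

The eight-product panel uses a stiffness ladder mirroring the real
products (E ≈ 378 … 49 kPa), with the softest product an exact
Mooney–Rivlin material so discovery can be exercised on a two-invariant
truth. All randomness flows from one seed; changing it changes noise,
never the generating parameters.

The survey generator plants a monotone latent link between standardised
log-stiffness and each feature (baseline 3, feature-specific slopes,
participant noise sd 0.8), discretised to 1…5 by thresholds at 1.5, 2.5,
3.5, 4.5. The brittleness slope (1.1) is calibrated by Monte Carlo so the
recovered product-level Spearman correlation with stiffness averages
≈ 0.86 for an 18-participant panel; zero-slope features provide null
features for type-I checks. Questionnaire responses are drawn to hit
normally distributed target totals (means 24.3 and 48.7).

What the generators do *not* emulate: rate dependence and genuine
viscoelastic hysteresis (the split is static), micro-structural
heterogeneity (bubbles, fibres), instrument under-travel, participant
response styles or product-order effects in the survey. Passing recovery
tests therefore demonstrates the pipeline's correctness, not robustness to
those real-data effects.

## Numerical notes and degenerate inputs

- Exponential-term arguments are capped (overflow raised with the
  offending term named) — relevant only for runaway internal weights.
- Training divergence (non-finite loss) raises with advice to lower the
  learning rate; the α sweep failing to reach exactly two terms raises
  with the full term-count profile.
- Rank-deficient least-squares designs (all points at λ = 1) raise a
  singular-fit error; constant stress curves yield NaN R²; constant inputs
  to Spearman raise.
- An equibiaxial input yields P₁₁ = P₂₂ exactly for any energy model;
  swapping (λ₁, λ₂) swaps the stresses.

## Known limitations

- The analysis is purely elastic; hysteresis is averaged away, not
  modelled. Rate effects and compressibility (relevant for bubbly
  plant-based products) are out of scope.
- The discovered-model alpha sweep selects *a* two-term model; with very
  noisy or soft products different seeds can select different pairs, which
  is why discovery results carry their seed and the selection profile.
- Goodness of fit for the worst-fitting products is sensitive to the R²
  convention and to which parameters are plugged in (mean-fit versus
  per-sample average); per-curve values there have large spread, and the
  package reports the spread rather than hiding it.
- Survey ANOVA ignores the repeated-measures structure (each participant
  rates all products); with n = 18 this inflates power slightly relative
  to a mixed model.
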