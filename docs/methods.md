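# Methods

## Scope and assumptions

The package models the reproduction of a single tomato flower at a fixed
developmental stage exposed to one constant-temperature episode. The cascade
assumes:

- tissue temperature equals air temperature (no microclimate offset);
- pollen number responds to temperature only — stress duration acts purely
  through the viability and germination fractions;
- each flower develops into one fruit (`c_flower_to_fruit = 1`); flower
  abortion is handled separately by the optional fruit-set quadratic;
- seed number is linear in germinated pollen and fruit mass is linear in
  seed number over the observed range (no saturation at high seed counts);
- the five functions are independent given their inputs, so they are also
  calibrated independently (per-function least squares), keeping error
  propagation identical between calibration and prediction.

The timing of the stress relative to anthesis (the sensitive window) is not
modelled; neither are whole-plant assimilate dynamics.

## Parameters

| group | parameter | default | units | role |
|---|---|---|---|---|
| pollen beta | μ | 5 | — | magnitude (estimated) |
| | T_b, T_opt, T_c | 13, 18, 48 | °C | base / optimum / ceiling |
| | T_0 | 1 | °C | dimensionless-difference scaling, kept explicit |
| | N* | 6.61 × 10⁴ | grains/flower | peak pollen number (measured) |
| viability | α_v; θ_v1, θ_v2 | 0.94; 0.78, −0.11 | —; —, d⁻² | vertex fraction; duration interpolation |
| germination | α_g; θ_g1, θ_g2 | 0.31; 0.34, −0.06 | —; —, d⁻² | idem |
| seed link | m₁, b₁ | 1.60 × 10⁻³, 2.23 | seeds/grain, seeds | slope, baseline |
| mass link | m₂, b₂ | 7.80 × 10⁻², 2.06 | g/seed, g | slope, parthenocarpic baseline |
| conversion | chamber, sample | 0.2 mm³, 200 µl | | haemocytometer count → grains/flower |

The shape exponents α, β of the beta curve are derived, not stored: the peak
constraint gives β = (ln N* − μ)/(δ₃ ln δ₁ + ln δ₂) and α = βδ₃. With the
defaults they evaluate to 0.2770 and 1.6621 (0.28 and 1.66 at two decimals).
Because the exponents are re-derived from the unrounded μ at every
evaluation, the curve's peak reproduces N* to machine precision; evaluating
with the *rounded* two-decimal exponents instead would move the peak by well
under 0.5%.

The fruit-mass unit is carried as a config label (`mass_unit`, default
"g per fruit") rather than interpreted as dry or fresh mass; the calibration
sources label it both ways and the package does not convert.

## Numerical choices and edge cases

- Outside the open interval (T_b, T_c) the beta curve is defined as exactly
  0, which also avoids fractional powers of negative bases. The degenerate
  parameterization δ₃ ln δ₁ + ln δ₂ = 0 (no finite exponent can satisfy the
  peak constraint) raises an explicit error.
- The duration interpolation p(D) = θ₁ + θ₂D² is a *latent* level and may be
  negative (the default viability calibration reaches −0.98 at D = 4 d);
  clamping happens only at the surface: fractions are clamped to [0, 1]. The
  lower clamp is part of the model definition; the upper clamp is a package
  design decision so that user-supplied parameter sets with α_max near 1
  cannot break the cascade ordering (the defaults never reach it).
- With the default parameters the germination surface clamps to 0 at, e.g.,
  30 °C for 4 days. The whole cascade then collapses to the baseline chain
  m₂·b₁ + b₂ ≈ 2.234 g. Scenario values of ~2.9 g quoted for that regime in
  the discussion of the original calibration are therefore not reproducible
  from the rounded published parameters; the package documents rather than
  patches this discrepancy, and no test asserts those scenario values.
  (Likewise, a figure caption of that calibration prints θ_v2 = −1.11 d⁻²
  where the parameter table prints −0.11; the table value is adopted — the
  caption value would drive the surface to deep negatives after a single
  day, inconsistent with the plotted surface.)
- Regimes outside the calibrated range T ∈ [14, 34] °C, D ∈ [0, 8] d are
  accepted (the curve is defined everywhere) but emit an
  `ExtrapolationWarning`.
- Nonlinear fits run `scipy.optimize.least_squares` from five fixed starting
  points spread over plausible ranges and keep the lowest objective;
  bounds are wide (μ ∈ [−5, 20], θ ∈ [−5, 5]²) and tolerances are scipy's
  defaults. Residuals are taken against the *clamped* surface, so fully
  clamped regimes contribute constant residuals and zero gradient — they are
  not excluded or special-cased.
- Observations are pooled to treatment means before fitting (pollen number,
  depending on temperature only, is pooled to temperature means); fits are
  therefore invariant to row order and to block/truss labelling. Raw-row
  fitting is available via `pool_means=False`.
- R² is computed as 1 − SS_res/SS_tot about the observed mean, also for the
  nonlinear fits; it can be negative. A constant response is fitted as a
  flat line with R² reported as 0 by convention.
- The aggregate error score is the unweighted mean of the five per-function
  root-mean-square errors over treatment means. The alternative reading
  (root of the pooled mean square across functions) is unit-incoherent —
  grains, fractions, seeds and grams cannot share one square — so the mean
  of per-function RMSEs is used, a warning flags the mixed units, and the
  per-function values are always reported alongside.

## The synthetic experiment

`generate_experiment` emulates the calibration experiment's statistical
structure: 10 treatments × 3 blocks, 4 plants/block × 3 trusses for the
pollen assays, 6 plants/block × 3 trusses for fruit traits, 9 flowers per
truss. Noise enters where the real measurement process introduces it:

- **haemocytometer counts**: grains in the counted 0.2 mm³ aliquot are
  Poisson around N_true × (0.2 mm³ / 200 µl) ≈ N_true/1000 (≈ 66 grains at
  the control), so the count-to-concentration conversion is exercised on
  integers. A negative-binomial switch (`count_dispersion > 1`) is exposed
  because true overdispersion of chamber counts is unknowable from summary
  data; Poisson is the default.
- **viability**: binomial on the grains actually counted in the chamber —
  the assay's real denominator.
- **germination**: binomial on a fixed assay size (default 100 grains per
  flower, config-exposed; the in-vitro assay scores fixed fields of view and
  its true denominators are not published).
- **seeds**: Poisson around the link-predicted mean.
- **fruit mass**: normal residual, default scale 0.9 g per individual
  fruit — chosen once as a realistic per-fruit spread consistent with
  reported box-plot dispersions. Note that because the generator *is* the
  model, simulated treatment-mean errors shrink as 1/√n and carry no
  structural component, so measured-vs-predicted RMSEs on simulated data are
  smaller than those reported for the real experiment; passing recovery
  tests demonstrates estimator correctness, not real-data fit quality.
- **block effects** default to 0 (the model ignores blocks); an optional
  relative block multiplier (1 + N(0, block_sd)) on pollen, seed and mass
  means supports robustness testing.

Setting every scale to zero makes the generator reproduce the deterministic
cascade exactly, which is what makes zero-noise recovery an exact test of
the fitting code. All randomness flows from one integer seed through
`numpy.random.default_rng`; a fixed seed reproduces the table bit for bit.

What the simulator deliberately does **not** reproduce: staining/imaging
artefacts, flower-stage timing and the sensitive window, truss-position
effects, correlations between traits measured on the same plant beyond the
shared cascade mean, and the unbalanced-block randomization details.

`recovery_study` chains generate → fit and reports signed relative errors
per parameter. At the default design and noise, a 100-replicate study puts
the median absolute relative error at ~2–3% for μ and the four θ parameters
(see `tests/test_acceptance.py`, which recomputes this).

## Design decisions that were genuinely open

- **Fruit-set quadratic**: its published coefficients are unavailable, so it
  ships without defaults and every yield computation requires explicit
  coefficients; the example file is labelled illustrative, interpolating
  reported point values (0.70 at 14 °C, 0.90 at 30 °C, 0.875 assumed at the
  control).
- **Seed-link units**: the slope term is read as the product
  m₁ · N_germ · c_flower→fruit (seeds/grain × grains/flower × flowers/fruit
  → seeds/fruit); numerically moot at the default c = 1 but the unit
  contract is kept explicit.
- **Cascade floor**: with zero germinated pollen the seed link still returns
  b₁ seeds and the mass link m₂·b₁ + b₂ ≈ 2.234 g — the model's floor is
  this value, not the bare mass intercept b₂.
- **Treatment-level link fitting**: pollen and fruit traits are measured on
  different plants, so the two linear links are fitted on treatment means,
  pairing the reconstructed mean germinated-pollen number with mean seed
  count, and mean seed count with mean fruit mass.

## Known limitations

- Single-episode, constant-temperature regimes only; no fluctuating
  profiles or multiple stress windows.
- The calibration is cultivar-specific (a dwarf tomato); applying the
  defaults to other genotypes requires re-estimation.
- μ is weakly identified away from the pinned peak (the curve's sensitivity
  to μ at the stress temperatures is ~0.04–0.14 on the log scale), so μ
  recovery leans on the precision of treatment means; sparse designs will
  widen its error considerably.
- No uncertainty quantification beyond Monte-Carlo recovery: the calibration
  reports no standard errors to propagate.
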