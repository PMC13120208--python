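# Methods

## Model overview

The package implements a screening-level inhalation risk assessment for
engineered nanomaterials. The causal chain is

    size-binned number concentrations (background, emission)
      → session averages → net emission (background subtraction)
      → mass concentration (spherical-particle conversion)
      → 8-h-equivalent TWA
      → exposure-adjusted concentration (ET/EF/ED/AT)
      → chronic daily intake → cumulative career dose → lifetime-averaged dose
      → margin of exposure (vs a point of departure)
        and hazard quotient (vs a reference concentration)

All stages are deterministic given their inputs; uncertainty enters only
through the input distributions of the Monte Carlo layer.

### Assumptions

- **Spherical particles at bulk density.** The number-to-mass conversion
  treats every particle as a sphere of the material's bulk density at its
  bin's midpoint diameter. Agglomerates and high-aspect-ratio materials
  (nanotubes, graphene platelets) have lower effective densities, so their
  mass concentrations are biased high — a conservative direction for a
  screening assessment.
- **Monodisperse shortcut.** When only a total number concentration is
  available (not the full distribution), the whole aerosol is placed at the
  material's nominal primary size (20 nm silver, 30 nm gold). This is the
  interpretation under which the published session totals and mass
  concentrations are mutually consistent.
- **Zero exposure outside the session.** The 8-h TWA scales the session
  concentration by session length over 480 min.
- **Independent inputs.** The Monte Carlo layer draws all inputs jointly
  independently — no input correlations and no stratification (plain Monte
  Carlo, not Latin hypercube).
- **The adjusted concentration is the intake concentration.** The composed
  chain feeds the ET/EF/ED-adjusted concentration into the intake equation,
  so the behavioural factors influence both the hazard quotient and the
  margin of exposure. Staged functions (`cdi`, `cdi_25`, `cdi_adj`) remain
  available for computing each step from any concentration the analyst
  prefers.

## Unit bookkeeping of the mass conversion

With diameters in nm, density in g/cm³ and number concentrations in #/cm³,
the per-bin mass is

    mass [µg/m³] = k · ρ [g/cm³] · CN [#/cm³] · (π/6) d³ [nm³],  k = 10⁻⁹,

since nm³ → cm³ contributes 10⁻²¹ and g per cm³ of air → µg per m³ of air
contributes 10¹². The constant is validated two ways: a per-particle
brute-force oracle with independent unit bookkeeping (tests, 10⁻¹²
relative tolerance) and the published session values (30 nm gold at
7.56 × 10³ #/cm³ → 2.06 µg/m³; 20 nm silver at 1.21 × 10⁵ #/cm³ →
5.32 µg/m³, both within 1%).

## Parameter defaults

| Parameter | Unit | Default | Distribution |
|---|---|---|---|
| Inhalation rate IR (male / female) | m³/day | 17.48 / 13.67 | uniform ± 2.81 / ± 2.28 |
| Body weight BW (male / female) | kg | 65.2 / 67.8 | uniform ± 0.301 / ± 0.261 |
| Exposure time ET | h/day | mode 6 | triangular 5 / 6 / 8 |
| Exposure frequency EF | days/yr | mode 63 | triangular 51 / 63 / 83 |
| Exposure duration ED | yr | mode 25 | triangular 20 / 25 / 30 |
| Life expectancy LE (male / female) | yr | 64.0 / 69.6 | point |
| Occupational period YE | yr | 25 | point |
| Conversion factor CF | mg/µg | 0.001 | point |
| Session length | min | 360 | point |
| POD (Ag / Au / graphene / MWCNT) | mg/kg/day | 53.7 / 536.7 / 0.98 / 3.02 | point |
| Rfc (Ag / MWCNT) | µg/m³ | 0.19 / 1 | point |
| NRV (Au) | #/cm³ | 20,000 | point |
| Densities (Ag / Au / MWCNT / graphene) | g/cm³ | 10.49 / 19.3 / 1.5 / 1.0 | point |

The deterministic chain uses the triangular modes as point values. The
point of departure enters risk characterisation only; silver and gold PODs
derive from in-vitro bronchial-epithelial response concentrations converted
by surface dose × 10⁴ (µg/cm² → µg/m²), a conservative unity-thickness
assumption (µg/m² ≈ µg/m³), division by 1000 to mg/m³, and the intake
form (`pod_from_surface_dose`).

### Divisor convention for the cumulative dose

The sex-specific rule divides the career dose by the sex's own life
expectancy (64.0 yr male, 69.6 yr female); this is the default. Published
dose tables are numerically consistent with a single 64.0 divisor for
both sexes, so an `as_printed=True` compatibility switch reproduces that
convention. Lifetime days are years × 365, with no leap days.

## Monte Carlo layer

- 10,000 iterations by default; at this size the coefficient of variation
  of the MoE median across seeds is below 2 % for the default silver
  configuration (checked over 10 seeds in the test suite).
- Percentiles use linear interpolation between order statistics
  (`numpy.percentile(method="linear")`), so medians and 95th percentiles
  are reproducible to the bit for a given seed.
- Constant (degenerate) outputs report SD exactly 0 and mean = p50 = p95 =
  the common value, rather than the rounding noise of a summed variance, so
  point-distribution runs collapse exactly onto the deterministic chain.
- Lognormal fitting is maximum likelihood on log-data (MLE variance,
  ddof = 0); AIC counts k = 2 parameters; the chi-square statistic uses 10
  equal-probability bins with expected count n/10 (degrees of freedom
  10 − 1 − 2 = 7). All-equal samples raise a degenerate-fit error.
- The airborne-concentration distribution for a scenario defaults to
  geometric mean = the reduced TWA with geometric SD = 2, a generic
  workplace-aerosol spread adopted because fitted parameters for the
  original sessions are unavailable; it is an assumption, not a
  measurement.
- Default seed 20260326; every simulation output records its seed, and
  assessment bundles embed a configuration hash and the package version.

## Sensitivity analysis

Influence is the Spearman rank correlation ρ between input and output
draws; "contribution share" is ρ²/Σρ² × 100 — the tornado-chart
convention of spreadsheet risk tools. Shares sum to 100 % by
construction; ties in ranks use average ranking; constant inputs are
flagged and assigned ρ = 0; a constant output is an error. Rows are
ordered by |ρ| with alphabetical tie-breaking, so orderings are
reproducible under a fixed seed. Because the measure is rank-based it is
invariant to strictly monotone transforms of the output.

Under the default configuration the concentration dominates MoE variance
(share > 85 %), with exposure frequency the leading behavioural
contributor — it enters the chain twice (adjustment and intake) — and
exposure time/duration above body weight.

## Synthetic session generator

Each timestamp's total number concentration is drawn lognormally (GM/GSD);
the total is apportioned across instrument bins by the CDF differences of
a lognormal number-size distribution over the bin edges (exact
discretisation, renormalised over the instrument range). The ground-truth
record carries the expected net total, expected per-bin net concentrations
and the closed-form mass concentration.

What it emulates: session-scale amplitude fluctuation, instrument bin
structure, background-dominated bins (which exercise the clamping path).
What it does not: temporal autocorrelation (draws are i.i.d.; the
session-averaging reductions are insensitive to it), counting-efficiency
and charging physics, coincidence losses, and size-dependent noise.
Passing the recovery tests therefore demonstrates correctness of the
reduction arithmetic under known statistics, not robustness to real
instrument artefacts.

Scenario presets set the emission GM so that the expected *net* total
equals the measured session total for each material, with the background
at one tenth of the emission (the monitored sessions were strongly
emission-dominated) and GSD 1.5 amplitude noise — generator choices, not
measurements.

## Numerical choices and degenerate inputs

- Bin midpoints are geometric means of the edges (log-spaced sizer
  channels); an arithmetic-mean option exists.
- Negative net bins are floored at zero and flagged; raw differences stay
  retrievable on the result object.
- Boundary verdicts: MoE exactly 100 (or 10,000 for genotoxic endpoints)
  classifies as low risk; HQ exactly 1 classifies as low.
- Session durations are restricted to (0, 480] min; exposure time to
  (0, 24] h/day; frequency to (0, 365] days/yr.
- HQ for materials without an Rfc is an explicit unavailable-benchmark
  error (reported as absent in tables), never silently zero.

## Problem sizes

The test suite runs Monte Carlo at n = 10,000 (including a 10-seed
stability check), synthetic recovery over 20 seeds of 360-timestamp
sessions, and property tests at 30–60 examples each; the full suite
completes in a few seconds. The analysis drivers use the same sizes.

## Known limitations

- Screening-level only: no toxicokinetics, no deposited-dose lung
  modelling, no benchmark-dose fitting, no dermal or ingestion routes.
- Bulk-density spheres overstate the airborne mass of carbon-based and
  high-aspect-ratio materials.
- The acute in-vitro origin of the silver and gold PODs makes the MoE a
  coarse instrument for chronic risk; the hazard quotient against an
  exposure-limit-derived Rfc is the more interpretable output here.
- No behavioural or protective-equipment modifiers are modelled.
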