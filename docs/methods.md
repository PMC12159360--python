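# Methods

## Overlap simulation and effective swath width

A patternator measurement gives the single-pass transversal distribution
of spray liquid: collected volume per groove on a regular lateral grid
(pitch 0.1 m by default). Field treatments superpose many parallel passes
spaced by the inter-lane distance *s*, so the simulated deposition is

    D(x) = Σ_k  p_k(x − k·s),   k = −(n−1)/2 … +(n−1)/2,

with `n = 7` passes by default and `p_k` the single-pass profile, mirrored
about its volume-weighted center on odd `k` when back-and-forth flight is
assumed (the aircraft reverses heading, so an asymmetric plume pattern is
reflected on alternate lanes). Uniformity is scored by the coefficient of
variation CV = sample standard deviation (n−1 denominator) / mean × 100 %,
and the effective swath width is the greatest spacing with CV strictly
below the threshold (15 % by default).

Conventions this package fixes where practice varies:

* **Swath grid.** Spacings are restricted to integer multiples of the
  groove pitch; this avoids interpolation artefacts in the superposition.
  `resample_profile` (linear interpolation, volume-conserving) is provided
  for finer sweeps but is off by default.
* **Evaluation window.** The CV is computed over a window one swath wide
  (at least two grooves) centered on the middle pass: `w = max(s/pitch,
  2)` consecutive grooves starting at the groove whose center is nearest
  to (pattern center − s/2), ties resolved upward. With 7 passes this
  window sees the periodic steady state; the first and last lanes are
  edge-affected and excluded by construction.
* **Mirroring.** The reflection center is the volume-weighted profile
  center snapped to the nearest half pitch, so mirrored grooves stay on
  the grid; for symmetric profiles mirroring is the identity. It can be
  disabled (`mirrored=False`).
* **Sample vs population SD.** The sample convention (n−1) follows sprayer
  -inspection practice, where the CV is computed from a finite set of
  collecting cylinders. At typical window sizes (≥ 20 grooves) the choice
  moves the CV by under 3 % relative.
* **Strictness and ties.** The criterion is strict (`CV < threshold`); a
  non-contiguous compliant band still yields its maximum spacing but
  raises a warning, since an interior spacing violates uniformity.
* **Trimming.** Profile extent is defined after removing leading/trailing
  grooves below 1 % of the maximum groove volume (configurable); tails of
  patternator data are noisy and would otherwise inflate the extent.

Conservation — total deposit equals `n_passes ×` profile volume — holds
exactly (float tolerance) for every spacing and mirroring mode, and the
whole CV curve is cross-checked in the tests against an independent
brute-force superposition written with a different mechanism.

## Lateral wind

The wind analysis projects the horizontal wind vector onto the flight
line's right-hand normal: positive values blow toward 90° (right of the
direction of flight), negative toward 270°. The projection is linear and
ignores the along-track and vertical components. Summaries use Tukey box
statistics: hinges at the 25th/75th percentiles by linear interpolation
between closest ranks (the convention of mainstream plotting libraries;
configurable), whiskers at the furthest datum within 1.5 × IQR of its
hinge. `pulse_stats` reports the signed sample of maximum magnitude and
the fraction of samples in a band (default 0 to −2 m/s). No ambient-wind
correction is applied; the measurement protocol relies on calm conditions
instead, and the synthetic generator, not the analysis, owns ambient wind.

## Fleet meta-analysis

Per-model effective swath widths are summarized by the same box engine;
regressions use the per-model *median* against total UAV width and MTOW.
Fits are ordinary least squares with classical standard errors (via
`scipy.stats.linregress`); no p-values are reported. Total propeller
working area is `rotor_count · π (d/2)²`. Lift-coefficient estimation is
out of scope.

## Survey extrapolation

Multiple treatments of a plot within a year count once (first record by
input order wins; conflicting areas raise a warning). Records flagged
non-agricultural or experimental are excluded. Slope bands default to
<18 %, 18–50 %, >50 % with an "unknown" band for missing slopes. The
national estimate multiplies the respondent area by the inverse response
rate *rounded to two decimals first*, then floors to integer hectares:
471 × round(1/0.28, 2) = 471 × 3.57 = 1681.47 → 1681 ha. Other operation
orders give 1682 ha; the rounded-factor-then-floor order is the package's
fixed convention. Estimates carry an upper-bound flag because
non-respondents may simply have had nothing to report.

## Deposition and efficacy

Raw tracer deposits (ng/cm²) are normalized by the tracer application
rate, removing the volume-rate difference between techniques (≈123 L/ha
UAV vs ≈378 L/ha backpack). Technique comparison is the ratio of mean
normalized ground deposit to mean normalized UAV deposit per canopy
region (median available via `statistic="median"`). Control efficacy uses
the Abbott convention, 100 × (1 − treated/control), chosen as the field's
standard where no formula is otherwise fixed; negative values are
reported as-is.

## Compliance rules

Weather: gusts above 5 m/s, visibility not above 1 km, and icing block
the operation; mean wind above 3 m/s and shade temperature at or above
25 °C are advisory. Both wind thresholds are strict (">"), following the
wording "exceeding"/"greater than"; the temperature bound is "less than
25 °C", so exactly 25 °C is already advisory. Safety distances compose by
maximum — drift default 20 m for field crops, grassland/meadows,
vegetables, strawberries, lawns and any herbicide treatment; a
product-specific distance replaces the default only when greater; 3 m
(6 m under direct payments) to surface waters; 10 m to bystanders for
MTOW > 10 kg — the governing distance is the largest applicable one.
Flight precision passes when the maximum absolute lateral deviation is at
most 0.5 m.

## Synthetic data

The generators emulate the structure of assessment data, not any real
machine:

* **Profiles** are Gaussian mixtures (one plume per nozzle; default four
  plumes at ±0.4 m and ±1.2 m, σ = 0.45 m, 4.88 L total on a 0.1 m grid),
  with exact per-groove Gaussian masses so volume is conserved to <0.5 %
  before noise, and optional multiplicative lognormal noise (unit mean).
  Gaussian plumes are the simplest shape producing the uni/bimodal
  profiles patternator work reports; real profiles are rougher and can be
  skewed by crosswind during the measurement.
* **Wind** is a stationary AR(1) (marginal mean/SD as given; lag-1
  autocorrelation 0.95, matching the second-scale integral timescale of
  ambient wind sampled at 10 Hz) plus a Gaussian-shaped lateral transient
  (default −1.5 m/s peak, σ = 1 s, the transit time of a machine passing
  the sensor's closest point at ≈3 m/s). Real downwash transients are
  asymmetric and turbulent; the generator captures timing and magnitude
  only.
* **Fleets** draw rotor count ∈ {4, 6, 8} and propeller diameter ∈
  [0.6, 1.4] m, then set MTOW = 14 kg/m² × propeller working area + N(0,
  4 kg) — the strong area–weight relation observed across homologated
  multirotors; no public regression equation exists, so the slope is a
  package convention. Median effective swath width scales as
  0.45·√MTOW + 0.8 m, placing mid-size machines in the 2.5–4 m range.
* **Surveys** assign each plot a crop from the requested mix, a canton,
  slope and area, one record per year, plus a repeat record with the
  duplicate probability.
* **Efficacy** draws normalized ground deposits per region (upper canopy
  1.0, near-bunch leaves 0.7, bunches 0.4 in arbitrary units) with
  lognormal scatter (CV 0.3), attenuates the UAV means by the region
  factors (defaults 1, 1/3.6, 1/7.1), and reconstitutes raw deposits via
  each technique's tracer rate. Severities are clipped normals with
  control > UAV > ground ≈ UAV+ground on average.

Because the generators share the analyses' structural assumptions,
passing recovery tests shows the estimators are consistent and correctly
implemented — not that real patternator, wind or trial data satisfy those
assumptions. Numeric results printed in the original assessments that
depend on undistributed registry data (per-model swath medians, wind
box values, trial severities) are not reproducible here and are treated
as documentation context only.

## Problem sizes and numerics

Default study sizes: 61-groove profiles swept over ~50 spacings with 7
passes; 500-sample wind series with 100-seed recovery runs; 30–50-model
fleets; 50 deposition samples per region and technique. Grid arithmetic
uses integer indices derived once from the pitch (tolerance 10⁻⁶ pitch)
to avoid float drift; degenerate inputs (all-zero profiles, constant
regression designs, zero means, empty groups) raise typed errors rather
than NaNs.
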