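# Methods

## Psychrometrics

Saturation vapor pressure uses the Magnus form over liquid water,
`es(T) = 0.6108·exp(17.27·T/(T+237.3))` kPa, valid −20…60 °C (inputs outside
that range raise). It reproduces the benchmark the rest of the package hangs
on: air at 32.2 °C and 29.4% RH has a VPD of 3.40 kPa. The formula lives in
one function so a Buck or Tetens variant can be substituted globally.

"Constant absolute humidity" during temperature elevation is implemented as
**constant vapor pressure** `e` (kPa). At fixed total pressure, `e` is the
water-amount proxy that is exactly conserved when the same air is heated;
mass-per-volume absolute humidity (g m⁻³) differs from it only through the
ideal-gas temperature factor (<5% across the sweep range). Conversions to
and from g m⁻³ are provided (`absolute_humidity`,
`vapor_pressure_from_absolute_humidity`) for users who prefer the
mass-based convention.

Two fixed pressures are defaults, not constants of nature: 98.0 kPa for the
growth chamber in the conductance formula and 94.9 kPa for the site in the
canopy integration. Both are arguments everywhere they appear.

## Drydown estimation

Per weighing interval, conductance is
`J = W_loss/(ΔT·A·VPD)·P`, with `W_loss` converted grams → mmol via the
molar mass of water, 18.015 g mol⁻¹ (the unit bookkeeping the headline
formula leaves implicit). Choices:

* **Interval RWC** is the mean of the endpoint RWCs — the unbiased midpoint
  for a flux computed from a difference across the interval.
* **g_min is the mean of J** over intervals whose mean RWC lies in the
  *inclusive* window [0.50, 0.80] (not a regression intercept): the plateau
  is read as a set of values to average. The OLS slope of J against RWC
  inside the window is reported as a diagnostic; |slope| above a threshold
  (default 5 mmol m⁻² s⁻¹ per unit RWC) flags — but does not reject — the
  estimate. Window bounds and the minimum occupancy (3 intervals) are
  configurable.
* Intervals with a mass *gain* beyond the noise tolerance are excluded, not
  clipped to zero.
* `ΔT` is the full span between weighings; the brief out-of-chamber weighing
  excursions are not subtracted (a dead-time correction can be applied by
  shortening `ΔT` upstream, but is off by default).
* Projected→evaporating area uses a sidedness factor, default 2 (exact for
  flat broadleaves). For conifer needles the true factor depends on
  cross-sectional geometry; it is a documented bias knob, not estimated.

Aggregation is hierarchical with equal weights at each level: leaves →
tree mean, tree means → species mean, species means → functional-group mean.
The SE at each level is computed from the entities one level down, so a
single-member group reports an undefined (NaN) SE rather than 0.

## Synthetic drydowns

The generator inverts the estimation formula: per internal step (60 s) the
leaf loses `g(RWC)·VPD/P·A·Δt` mmol. Conductance starts at `stomatal_g0`
(default 12 mmol m⁻² s⁻¹ — dark, detached leaves keep only a modest fraction
of g_max open) and decays exponentially in RWC, reaching the cuticular floor
`true_gmin` at `closure_rwc` (default 0.80; the decay constant gives ~5
e-foldings across the transition, so the floor is met to <1%). Below
closure, conductance is exactly `true_gmin`. The transition shape is a
modelling choice — only completeness of closure below 80% RWC is
constrained by observation — and exponential was chosen for smoothness;
`closure_rwc = 1.0` produces a pure-plateau leaf for exact-recovery tests.

Balance noise is i.i.d. Gaussian per weighing (default sd 0.2 mg, the
precision of the chamber balance; the semi-automated box balance would be
50 mg), truncated at ±3 sd so no weighing reports an impossible mass gain;
the first weighing is noiseless because it defines the saturated reference.
Default leaf: 0.25 g dry mass, 0.8 g mobile water, 0.0075 m² two-sided area
(SLA 15 m² kg⁻¹), weighed every 2.5 h for 30 h — under these conditions the
RWC trajectory crosses the whole 0.80–0.50 window with ~6 plateau intervals.

What the generator does **not** emulate: within-leaf heterogeneity, chamber
humidity drift, rehydration artifacts, epidermal shrinkage reopening stomata
below 50% RWC. Passing recovery tests therefore demonstrates correctness of
the estimator under the model's assumptions, not robustness to those field
artifacts (which the RWC window is designed to sidestep).

## Temperature response

The exponential model `g_min = a·exp(bT)` is fitted by nonlinear least
squares initialised from log-linear OLS (≥4 distinct temperatures required).
The segmented model is a continuous two-segment line: exhaustive breakpoint
search at 0.1 °C resolution over the interior of the observed range (10%
edge margins), golden-section refinement between the best grid neighbours,
and an F-test (2 extra parameters: slope change and breakpoint) against the
single line at α = 0.05. Because the breakpoint is searched, the F-test is
nominally anticonservative; with the edge margins and the panel sizes used
here its empirical size measured by simulation stays below the nominal level
(the suite checks ≤10% on 200 null replicates). A best breakpoint on the
search edge, or a single line that already fits to machine precision,
returns a "no interior breakpoint" result instead of an exception. The
breakpoint SE is a seeded nonparametric bootstrap (default 1000 resamples).

Both model families are always available; the exponential is the default
forward model for canopy simulation (it is smooth and monotone, and the
bi-linear model agrees with it in the region the data constrain). Campaigns
and years are pooled without a covariate.

## Trait analysis

`SS = L·W` (guard-cell length × width of the pair, µm²) and
`f_gc = (π/2)·W·L·SD` with lengths in mm and density in mm⁻² — the width in
the formula is the **pair** width, matching the morphometric convention
used for the size metric. Values of f_gc above 1 indicate unit mistakes and
are flagged. Pearson correlations against g_min are computed with a
per-trait log10 policy (default: stomatal density, stomatal size and g_max
are logged; thickness and SLA are not) surfaced as a config flag rather than
hidden in code. Raw per-trait p-values are reported; a multiple-testing
option exists but defaults off, matching common practice for small
cross-species panels.

## Canopy integration

A left-Riemann sum at the native 5-min step over 08:00–20:00 (144
intervals): `Σ g(Tᵢ)·VPDᵢ/P·ΔT·R`, converted mmol → litres with
18.015 g mol⁻¹ and density 1.0 g mL⁻¹. Leaf temperature equals air
temperature and boundary-layer conductance is neglected — both stated
simplifications of the protocol this package implements. `R` is defined on
projected leaf area while g_min is per two-sided area; the scaling relation
is applied literally (area-basis factor 1 by default) with the factor
exposed on `CanopySpec` for users who want to reconcile the bases.

Elevation adds `delta` to every temperature sample and carries the vapor
pressure series over bit-identically; RH is recomputed (capped at 100% with
cap positions recorded). The scenario sweep runs `delta = 0, 0.1, …` until
the day's maximum reaches 50 °C — 179 scenarios from a 32.2 °C base day.
Halving the time step moves smooth-climate daily totals by <0.5%; for a
constant climate the sum equals the closed-form product to rounding
(g=1, VPD=1, P=94.9, R=100 over 12 h → 0.8201 L m⁻²).

The synthetic hot day is a half-sinusoid in temperature (peak 14:00) with
constant vapor pressure chosen so RH bottoms at the target minimum exactly
at the temperature peak. It reproduces a measured day's *extremes* (32.2 °C,
29.4%, 3.4 kPa), not its exact trajectory — so absolute per-species daily
totals computed from it are approximations, and the analysis driver reports
the cross-species spread it actually computes (which, with fixed season-mean
conductances instead of per-species temperature-response fits, is larger
than the spread obtained with fitted g_min(T) models).

## Problem sizes and determinism

Recovery rates are estimated with 200 seeded drydown replicates, breakpoint
coverage with 100 and null calibration with 200 segmented fits on 24-point
panels — sizes at which the Monte-Carlo error on the reported percentages is
a few points at most. All generators take explicit integer seeds and are
bit-reproducible; the pipeline records seed, config hash and stage timings
in its run metadata.

## Known limitations

* The needle projected→total area factor and the R/g_min area-basis factor
  are documented knobs, not estimated quantities.
* The breakpoint F-test is not a Davies-type corrected test; near-edge
  breakpoints are excluded by the search margins rather than corrected for.
* The drydown simulator is the estimator's own forward model inverted;
  recovery tests are internal-consistency checks by construction, and the
  hand-evaluated conductance example and closed-form integration oracle are
  the independent anchors.
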