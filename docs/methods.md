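# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, and what the synthetic-data tests do and do
not demonstrate about real tracking data.

## Synthetic deployment generator

The generator produces tracking data with exact ground truth so that
every downstream stage can be scored against what actually happened.

**Movement.** A four-state Markov chain at 1-s resolution — floating,
stopped, commuting, foraging/searching — with a correlated random walk
per state: per-second speed ~ Normal(mean, sd) clipped at 0, heading
increments ~ von Mises(0, κ). Defaults (speed mean/sd in m/s; κ):
floating 0.3/0.15, κ=2000 (slow, directional surface drift); stopped
0.2/0.1, κ=0.4 (jittering in place); commuting 10/1.5, κ=3000 (fast,
straight); foraging 8/1.5, κ=5 (fast, tortuous with ~5-s heading
persistence). The κ values are chosen so the low/high speed × turn
quadrant structure survives thinning to the 10-s and 5-min fix schedules:
per-second heading diffusion compounds over a sampling interval, so a
"straight" state needs κ on the order of the interval length in seconds.
Transition-matrix defaults give dwell times of roughly 15–30 minutes.

**Trips.** Timelines alternate colony rest (exponential, mean 2 h) and
foraging trips (exponential, mean 4 h). A trip's random walk is closed
back onto the colony by removing its net drift in proportion to distance
travelled per second, so fast flight steps absorb the correction and
floating/stopped fixes keep their true near-zero speeds. This is a
simulation convenience, not a behavioural model: real return legs are
directed flight, which the closure only caricatures.

**Sampling.** Fixes are emitted at the 300-s base cadence, switching to
10-s bursts while the bird is inside a geofence polygon; the schedule
stratum of each fix is recorded as truth for the rate-splitting test.

**Sensors.** The synoptic sea-level pressure field is an AR(1)-in-time
anomaly (hourly lag-1 autocorrelation 0.98, marginal sd 6 mbar by
default) plus AR(1) east–west and north–south linear gradients, on a
30-km grid; the "true" P₀ at a fix is defined as the nearest-node,
nearest-hour field value — i.e. the field is treated as piecewise
constant at its native resolution, which makes calibration-recovery
tests exact instead of being limited by interpolation mismatch. Tag
pressure is the mean of 10 noisy readings (per-reading sd 0.3 mbar) of
the barometric pressure at the bird's true height, plus a constant
sensor bias. GPS altitude is the true MSL height plus Gaussian noise
(sd 5 m) and, with probability 0.01, a Student-t(2) outlier scaled by
100 m — producing the extreme raw altitudes (±1000 m and beyond) that
real GPS tracks show. The GPS error magnitudes are fixtures, not
measurements. Tides are sums of harmonic constituents above Chart Datum
(defaults: 1.5 m at 12.42 h and 0.5 m at 12 h over a 3-m datum offset).

## Behavioural clustering (EMbC)

A 4-component bivariate Gaussian mixture on (speed, |turn|), fitted by
EM (scikit-learn's engine, run one warm-started iteration at a time so
the log-likelihood trace is available and its monotonicity is asserted
in tests). Initialisation is k-means++ on standardised variables with a
fixed seed; the covariance floor is 1e-6. Components are labelled by
their means' position against per-variable delimiters (the midpoint
between the two low and the two high component means): low/high speed ×
low/high turn maps to floating, stopped, commuting, foraging/searching.
Before fitting, each variable must be bimodal (2- vs 1-component BIC
margin > 10) — without a real low/high split the quadrant labels would
be arbitrary, and restarting cannot fix inseparable data; after fitting,
collapsed weights (< 1e-3), floor-level covariances, or a non-bijective
quadrant assignment trigger a reseeded restart (max 5). Ties in the
maximum posterior go to the lower component index. Behavioural smoothing
from the reference EMbC algorithm is deliberately omitted: only the four
labels and the stopped∪floating union are consumed downstream.

## Pressure calibration and altimetry

The conversion `h = (kT/mg) ln(P₀/P)` uses the tag's own temperature by
default (a switch substitutes the field's 2-m temperature). The relation
is sometimes printed with the argument order inverted (`ln(P/P₀)`),
which would make heights below-sea-level negative-signed; this package
uses `ln(P₀/P)` so lower pressure aloft gives positive altitude.

Calibration offsets come from floating bouts (maximal runs of
stopped/floating fixes per individual). For each bout the offset is
derived from per-fix differences `tag pressure − model P₀(fix)` — pairing
each surface reading with the model value it will later correct, so a
synoptic trend across the bout cannot leak in. Because altitude can only
*lower* the sensed pressure, fixes genuinely on the water form the upper
edge of those differences; the offset is the median of the differences
within 1 mbar of the bout maximum, which makes a bout robust to airborne
fixes that behavioural misclassification sneaks in. Pipelines discard
bouts with fewer than 3 usable fixes (a single-fix bout has no
redundancy against misclassification); the threshold is configurable.
Offsets are carried forward stepwise (no interpolation — the correction
is causal) and expire one day after the bout; stale fixes are excluded
from height analysis. Offsets beyond ±50 mbar are flagged as sensor
faults and ignored.

Tidal referencing: monthly MSL above Chart Datum is the mean of daily
mean tide heights (calendar months, UTC); `h_MSL = h_surface +
(tide(t) − MSL_month)` with the tide matched to the nearest 15-min
gauge sample. GPS altitudes are already MSL-referenced and pass through,
except for an optional, disabled-by-default de-biasing stage that
subtracts each individual's median floating-bout GPS altitude (a
stand-in for receiver-level GPS calibration; it needs ≥ 20 bout fixes).

## Height distributions and method comparison

Flight-state heights (commuting and foraging/searching only; floating
and stopped fixes never enter) are summarised per method × rate ×
colony × year, and turned into 1-m-band proportions on [0, 500) m by a
Gaussian-kernel density reflected at 0 — measurement error around the
sea surface contributes mass near zero instead of being truncated —
with band masses computed exactly from the kernel CDF. The bandwidth
parameter is the kernel standard deviation (default: Silverman's rule;
the pipeline uses 2 m). A raw binned mode exists as a switch.

The method comparison emulates a gamma GLMM with a per-individual random
intercept: a gamma-family GEE with inverse (canonical) link and
exchangeable within-individual correlation, which targets the same
marginal method contrast while accounting for repeated measures per
bird; a log link is available. Responses are shifted to strictly
positive support by `1 − floor(min)` when needed, and the shift is
recorded so link-scale estimates remain interpretable. Pairwise
contrasts are estimated marginal mean differences on the link scale
with a single-step max-|Z| multivariate-normal adjustment over the
contrast family (the same family-wise logic as Tukey-adjusted emmeans);
simulation tests verify ~5% type-I error and family-wise error control.
The time-since-calibration diagnostic fits a Huber-robust line to
|GPS − altimeter| versus staleness hours and reports a bootstrap
percentile CI for the slope.

## Collision risk (Band Option 3)

A bird is a box (length L along track, wingspan W across) crossing the
vertical rotor plane horizontally at height y relative to the hub and
offset x from the axis. At crossing radius r the blade presents depth
`c(r/R)·sin γ` along track, the bird occupies the plane for
`τ = (depth + L)/v`, each of b blades sweeps Ωτ during that window, and
the wingspan subtends an arc Δθ at radius r, giving
`p(x, y) = min(1, b(Ωτ + Δθ)/2π)` for a uniform random rotor phase.
The chord average of p is computed by Gauss–Legendre quadrature for the
smooth sweep term plus a closed-form antiderivative for the arc term —
the arc peaks sharply (width ~ max(|y|, W) metres out of a chord of
hundreds) and defeats plain quadrature; the p = 1 cap near the hub is
resolved by bisection. Option 3 weights each 1-m band's risk by the
flight-height proportion d(y) and the exposure factor
`w(y) = 2·chord(y)/(πR)`, normalised so a uniform-over-span distribution
recovers the disk-averaged risk. Expected monthly collisions scale by
aerial density (birds/km² in flight), flight speed, month hours,
operational proportion, activity factor, turbine count and
`(1 − avoidance)`. An event-based Monte Carlo blade-interception
simulation (per-blade rotation delays; handles overlapping windows
without the analytic cap) lives in the test suite as the independent
oracle; production always uses the deterministic integral.

The 12 farm configurations share a 430-MW total: hub height (70–140 m)
and rotor radius (40–110 m) increase linearly, per-turbine capacity
scales with rotor area (~8 MW mid-range), the turbine count is
`round(430/per-turbine MW)` with the rated value trued up so every farm
totals exactly 430 MW, tip speed is held at 80 m/s and max chord at 6%
of the radius. Bird parameters are gull-like fixtures: length 0.58 m,
wingspan 1.42 m, speed 13 m/s, avoidance 0.995, activity factor 1;
density defaults to 2 birds/km². Large-array wake corrections and wind-
direction weighting are out of scope. Collision-estimate groups are
compared with Tukey's HSD (scipy).

## Pipeline failure handling

A sampling-rate stratum whose pooled speed/turn data lack the low/high
bimodal structure (after the per-individual screen) cannot be
behaviourally annotated; the pipeline drops that stratum, records the
dropped fix count in the manifest, and continues with the other stratum.
A group where no stratum is classifiable, or any later stage error,
aborts the run with the failing group and stage named.

## Problem sizes and determinism

The demo pipeline simulates 2 colonies × 2 years × 3 individuals × 10
days (~75 000 fixes, ~50 000 offshore), chosen to exercise both sampling
strata and all four colony-year groups while a full run completes in a
couple of minutes. The calibration-recovery study uses a single 30-day
deployment at 30-s sampling (~86 000 fixes). Monte Carlo oracles use
10⁶ transits per single-transit check and 10⁷ per farm-level check.
Every stage derives its RNG stream from one pipeline seed; identical
seeds reproduce identical outputs byte for byte.

## What passing tests do and do not show

The generator produces the *structure* real data would have (bimodal
speed/turn, dual schedules, drifting pressure, heavy-tailed GPS error,
tides) but idealises much: no wind-dependent flight, no battery/solar
duty cycling, no GPS horizontal error, piecewise-constant pressure
truth, temperature sensed without error, and a caricatured return-leg
geometry. Recovery of injected biases here demonstrates that the
*method chain* is correct and self-consistent — not that real ERA5
fields, real tide gauges, or real gull behaviour satisfy the method's
assumptions. In particular the altimeter-vs-GPS collision gap in the
demo reflects simulated misclassification pollution of calibration
bouts, not the field phenomenon, and its sign need not match any
particular real deployment.

## Known limitations

* The gamma GEE is a marginal-model stand-in for a conditional
  random-intercept GLMM; with strong frailty the link-scale contrast
  magnitudes differ from a conditional fit, though the test decisions
  agree under the simulated conditions.
* Floating-bout calibration assumes the behavioural labels find genuine
  on-water periods; species that rarely float cannot be calibrated
  (such individuals are screened out by the bimodality check).
* Geoid–ellipsoid separation, humidity-corrected virtual temperature
  and in-field barometer calibration are not modelled.
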