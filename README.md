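# altiflight

Seabird flight heights from GPS and barometric altimetry, and what the
difference between the two methods does to offshore-wind collision-risk
estimates.

## The problem

Collision risk models (CRMs) for offshore wind farms need flight-height
distributions measured relative to mean sea level (MSL). Bird-borne tags
offer two routes to a flight height:

* **GPS altitude** — geoid (≈ MSL) referenced, but with heavy-tailed error
  at low sampling rates;
* **barometric altimetry** — tag pressure `P` converted to height above
  the sea surface through the barometric relation

  `h = (kT / mg) · ln(P₀ / P)`

  with `k = 8.31432` N·m·mol⁻¹·K⁻¹, `m = 0.0289644` kg·mol⁻¹,
  `g = 9.80665` m·s⁻², `T` the tag temperature (K), and `P₀` the sea-level
  pressure. `P₀` must be known at the bird's place and time; this package
  anchors it on a gridded reanalysis-style pressure field corrected by an
  additive offset measured whenever the bird sits on the water.

The pipeline implements the full chain for gull-like trajectories:

1. **synthetic** — a ground-truth deployment generator (4-state Markov
   movement, dual 5-min/10-s sampling, drifting synoptic pressure field,
   sensor bias and noise, heavy-tailed GPS error, harmonic tides);
2. **preprocessing** — trip segmentation around the colony, offshore and
   platform filters, speed/turn trajectory metrics, sampling-rate strata;
3. **behaviour** — expectation–maximisation binary clustering (EMbC) of
   speed × |turning angle| into stopped / floating / commuting /
   foraging-searching, and extraction of on-water ("floating") bouts;
4. **altimetry** — bout-anchored calibration of `P₀` with a one-day
   staleness limit, barometric conversion, and tidal referencing of
   surface heights to monthly MSL;
5. **heights** — summaries, reflected-KDE 1-m-band height distributions,
   and a gamma-family mixed comparison of methods (GEE with exchangeable
   within-individual correlation, Tukey-style adjusted contrasts);
6. **crm** — Band Option 3 collision risk over 12 parametric 430-MW wind
   farm configurations, with Tukey HSD comparison of collision estimates.

## Worked example

```python
from altiflight.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=11))
print(bundle["summary"].groupby(["rate", "method"])["mean"].mean().round(1))
print(bundle["collision_estimates"].groupby("group")["collisions"].sum().round(1))
```

prints (two simulated colonies × two years, ~76 000 fixes):

```
rate   method
10-s   Altimeter    31.4
       GPS          32.9
5-min  Altimeter    31.1
       GPS          32.1
Name: mean, dtype: float64
group
Altimeter_10-s     2082.4
Altimeter_5-min    2163.5
GPS_10-s           2210.6
GPS_5-min          2277.4
Name: collisions, dtype: float64
```

The first block is the mean flight height (m above MSL) per method and
sampling rate over flight-state fixes; the second is total expected
collisions (birds per month, summed over the 12 farm configurations and
May–August) computed from each method's estimated height distribution at
a fixture density of 2 birds/km² and 0.995 avoidance. Small systematic
height differences between the methods translate into visibly different
collision totals — the core sensitivity the package quantifies.

A CLI mirrors the library: `altiflight simulate`, `altiflight run`,
`altiflight crm` (see `altiflight --help`).

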