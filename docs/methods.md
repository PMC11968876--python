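# Methods

This note records the models, parameter choices and numerical decisions
behind `kelpmhw`, and what the synthetic experiments do and do not
demonstrate about real data.

## Marine-heatwave model

Detection follows the standard fixed-baseline percentile definition. For a
daily SST series T(t):

* **Climatology.** For each day-of-year d (366 slots, leap-calendar
  indexing), the seasonal mean μ(d) and the 90th percentile T₉₀(d) are
  estimated from all baseline observations within ±5 days of d, pooled
  circularly across the year boundary and across the baseline years
  1983–2012, then smoothed with a 31-day circular moving average.
  Percentiles interpolate linearly between order statistics. The ±5-day
  window (11-day pool), 31-day smoother, 90th percentile, 5-day minimum
  duration and 2-day maximum gap are the field-standard defaults for this
  definition; all are exposed as parameters.
* **Events.** Maximal runs of days with T strictly above T₉₀ (ties do not
  count — otherwise a constant series would be one endless event), of
  length ≥ 5 days; qualifying runs separated by ≤ 2 below-threshold days
  merge into one event spanning the gap. Missing days break runs and are
  excluded from climatology pools (a warning is logged when a pool is
  mostly missing).
* **Intensity.** Cumulative intensity sums T(t) − μ(doy(t)) over every day
  of the event span, gap days included; annual cumulative intensity
  attributes each event day to its own calendar year, so a Dec/Jan event
  splits between years. Anomalies are measured against the seasonal mean,
  not the threshold, matching the usual "cumulative intensity" metric.
* **Calendars.** Dates are proleptic Gregorian with leap days. Feb 29 maps
  to slot 60 and shares the pooled window of Feb 28/Mar 1; 365-day model
  calendars simply never populate slot 60.

A deterministic seasonal cycle can graze its own smoothed threshold near
the seasonal peak (the smoother mixes shoulder percentiles into the peak),
producing one shallow event per year of order 1 °C·day. This is a property
of the definition, not an implementation artifact; tests pin the behaviour
and real, noise-driven events are one to two orders of magnitude larger.

## Observed and model branches

Contemporary exposure (2001–2020 medians) comes from the observed-product
branch. Projected exposure uses model runs whose baseline climatology is
taken from the *model's own* historical run (1983–2012), never from
observations, so projected-to-contemporary comparisons are
modelled-vs-modelled on the model side. Exposure records carry an
`observed`/`model` provenance tag and the aggregation refuses to mix them.

Model preparation, in order: bilinear regrid to the 0.25° analysis grid;
additive delta correction per calendar month toward the historical
ensemble-mean climatology over 1983–2014 (variants: day-of-year or single
annual offset, selectable; monthly is the default because the delta is
then a per-month constant that preserves each model's daily variability
exactly and makes the correction idempotent). The order of regridding and
correction is immaterial for additive monthly deltas and is asserted by a
test. Kelp cells with no model value are filled with an
inverse-distance-weighted mean (power 2) of valued cells within a radius
of two *source-model* grid cells — the scale on which a coarse ocean model
can genuinely lack water — using great-circle distances on the authalic
sphere. Unfillable cells are reported, logged, and excluded from both
branches of any ratio so pixel populations stay comparable.

Aggregation order is fixed as: median over period years per model →
median across models per cell → mean across cells per region (with 5th and
95th percentiles, type-7). Pooling years × models before the median is a
defensible alternative; the chosen order matches "mean across ensemble
medians" reporting and is what the tests freeze. Latitude bins are
half-open [k, k+1) on floor(latitude).

## Synthetic world

The generators produce inputs with the statistical structure the method
assumes, not geophysical realism:

* **SST.** A single sinusoidal seasonal cycle (amplitude 4 °C, mid-August
  peak) + piecewise-linear warming trend with a 2015 pivot + AR(1)
  anomalies (φ = 0.7, marginal sd 0.5 °C), plus optional injected heatwave
  blocks with exact, known anomalies. With trend 0 and the baseline equal
  to the simulated span, ~10% of days exceed the threshold by
  construction; on unit-Gaussian anomalies T₉₀ − μ ≈ 1.28 °C (the Gaussian
  90% quantile) — both are calibration tests.
* **Ensemble.** Models share the base signal and a fixed spatial pattern,
  and add per-model constant biases (drawn once, sd 0.5 °C) and
  independent AR(1) realisations. A scenario run reuses its model's noise
  path, so it continues the historical run exactly at the pivot. Default
  scenario trends 0.012 / 0.021 / 0.039 °C yr⁻¹ (SSP1-2.6 / SSP2-4.5 /
  SSP5-8.5, from their approximate end-of-century warming levels spread
  over 2015–2100) and 0.010 °C yr⁻¹ historical.
* **Geometry.** A wiggly meridional coastline; kelp pixels as 30 m squares
  (Landsat footprint) 0.1–2 km offshore; MPAs as coastal rectangles
  2–15 km across with LFP scores drawn from a configurable weight vector;
  countries as latitudinal slabs, subdivided into ecoregions and grouped
  into realms, so every pixel lies in exactly one region per level.

What passing tests therefore show: the algorithms are correct (oracle
equivalence, conservation, calibration) and the pipeline recovers known
injected signals (event blocks, biases, trend orderings). What they do not
show: skill on real SST (no fronts, no ENSO-scale variability, no
observational error) or realism of absolute exposure magnitudes — the
fold-change ratios of the synthetic study are properties of its noise and
trend settings, not predictions.

## Protection overlay

Intersections run on unprojected WGS84 coordinates; areas use the
spherical line-integral formula on the authalic sphere (R = 6 371 007 m)
and are reported in hectares. Edges are straight in lon/lat rather than
great circles — an O(edge²) difference cross-checked against an
independent geodesic engine at feature scale (< 0.01%). Geometry
validation (repair, else removal with logging) precedes the spatial-join
prefilter; the prefilter is a bounding-box join, conservative by
construction (false positives resolve to empty intersections downstream,
false negatives are impossible). The nested split assigns kelp to a single
jurisdiction (largest-area rule for boundary spanners, logged) and copies
an MPA into every jurisdiction whose kelp envelope it touches, which makes
the split provably equivalent to the unsplit all-pairs intersection — the
property the oracle test checks. Jurisdiction tasks are independent;
parallel and sequential modes produce identical, deterministically sorted
records.

Where MPAs of different tiers overlap the same kelp, the area counts once
toward the highest tier (geometric union per tier minus higher tiers).
Reporting categories independently would double-count habitat;
the precedence rule is configurable in the summary stage, where target
flags can be evaluated on "high" alone (default, conservative) or
"high + moderate". Unscored MPAs must arrive with an explicit category;
nothing is imputed. The threat-versus-protection join excludes
less-protected MPAs from its protection columns (they restrict little)
and flags ecoregions with ≥ 30% effective protection and below-median
exposure as refugium candidates.

## Problem sizes and determinism

The bundled study (analysis scripts and the acceptance script) uses a
3°-wide coastal domain, 80 kelp pixels (~26 analysis cells), 10 MPAs, a
5-model ensemble with three scenarios, and daily SST 1983–2100; tests use
smaller worlds with proportionally shortened historical/scenario spans
and period definitions. These sizes keep a full run in tens of seconds
while exercising every code path (including IDW fill and cross-boundary
features); all counts, spans and periods are configuration, so larger
experiments are a config change, not a code change. Every random draw
descends from one named seed; reruns reproduce byte-identical outputs,
which the run manifest verifies with content hashes.

## Known limitations

* Planar (lon/lat) polygon intersection with spherical areas — adequate at
  metre-to-kilometre feature scale, not for basin-scale polygons.
* No quantile-mapping or trend-preserving bias correction; the additive
  delta preserves model variability but also model trend biases.
* No event categorisation (moderate/strong/severe), onset/decline rates,
  or duration-based exposure metrics.
* The synthetic coastline yields one-pixel-deep kelp cells; real kelp
  rasters have contiguous patches, so prefilter savings are understated.
* MPA effectiveness beyond fishing restriction (enforcement, budget,
  stage of establishment) is out of scope, as are non-fishing regulated
  activities.
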