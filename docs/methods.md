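# Methods

## The budget model

The analysis treats a river catchment's annual nutrient export as the sum
of two stocks measured over one hydrologic year:

* **plant-bound pool** — the peak standing floating-vegetation cover at a
  downstream choke point, converted to dry biomass and then to tissue
  nitrogen or phosphorus mass;
* **waterborne load** — mean annual discharge times the mean digestible
  nutrient concentration from quarterly surface-water sampling.

The *plant sink fraction* is the pool as a percentage of their sum. The
model's core assumptions, and what they buy:

1. **Peak cover ≈ annual plant export.** Where seasonal flows trap mats
   and then flush them (backwater confluences, reservoir surfaces), the
   annual maximum cover is exported roughly once per year. Choke points
   are not 100%-efficient traps, so this *underestimates* plant-bound
   export; the budget is deliberately conservative on the plant side.
2. **One year, one stock.** No growth kinetics or within-year uptake
   dynamics are modelled; the comparison is an annual stock ratio.
3. **Concentrations are "digestible", not total.** Peroxidisulfate
   digestion of unfiltered water under-recovers clay-bound particulate P
   when samples settle; loads may therefore be slight underestimates in
   clay-rich systems. Nothing corrects for this; outputs keep the
   "digestible" label.
4. **Units.** The load conversion uses a 365-day year:
   1 m³ s⁻¹ × 1 µg L⁻¹ = 0.031536 Mg yr⁻¹. All pools in Mg, areas in
   km², biomass in kg dry weight m⁻², tissue content as dry-weight
   fraction.

## Trait synthesis and its defaults

Plant biomass per area and tissue N/P content come from across-study
literature syntheses: arithmetic mean, standard error = sd/√n. The
primary literature tables are not shipped; `data/defaults.yaml` instead
carries **calibrated stand-ins** — values solved to reproduce the
published per-area nutrient densities and envelope widths:

| parameter | default | units | why |
|---|---|---|---|
| biomass per area | 2.0 (rel. SE 0.13, n=15) | kg dw m⁻² | mid-range of published Water Hyacinth mat densities; with the content values below it yields 9.67 g P m⁻² and 47.8 g N m⁻² of cover |
| P content | 0.004836 (rel. SE 0.076, n=17) | fraction dw | calibrated so pool(5.5 km²) ≈ 53.2 Mg P |
| N content | 0.02391 (rel. SE 0.09, n=14) | fraction dw | calibrated so pool(5.5 km²) ≈ 263 Mg N; the 0.09 relative SE reproduces the published N confidence intervals at all three sites, where 0.10 overshoots the lower bounds |

A user CSV of trait records (`synthesize_traits`) overrides all of them.

## Uncertainty envelope

Pool uncertainty compounds the two relative standard errors
multiplicatively: `env = pool · (1 ± r_B)(1 ± r_c)`, then the sink
fraction is re-evaluated at the envelope bounds with the load held
fixed. Two readings of "combine the two standard errors" were on the
table; the compounded-factor form is used because it is the only one
that produces the *asymmetric* intervals the calibration targets show (a
symmetric ± product has no real solution for those bounds). The envelope
is a sensitivity band, not a formal confidence interval.

`monte_carlo_sink_interval` cross-checks it: biomass and content drawn
as independent normals at their synthesis means/SEs, propagated per-draw
to the sink fraction; the mean ± 1 sd interval of the draws agrees with
the analytic envelope to within ~1 percentage point for relative SEs up
to ~0.15. The two intervals answer slightly different questions (1-sd
spread of a product distribution vs compounded worst-case factors), so
exact agreement is not expected.

## Discharge

Ungauged catchments get mean discharge from a rating curve `Q = a·A^b`
fitted by OLS on log Q vs log A over nearby gauge stations (statsmodels;
RMSE reported in log space). Log-space fitting weights relative errors,
appropriate when station areas span orders of magnitude. Whether to fit
in log or linear space was an open choice; log-space is the field
default for power-law scaling relations and is what the fit-recovery
tests assume. Observed per-site discharges, where available, are taken
as inputs rather than re-predicted.

## Seasonality summaries

Cover observations are composited into calendar-aligned two-month bins
(Jan–Feb … Nov–Dec) taking the per-bin **maximum**: peak biomass, not
average greenness, is the export proxy. Bin alignment and the max
statistic were unconstrained choices; calendar alignment keeps bins
comparable across years. Annual peaks take the month of the yearly
maximum with ties broken to the earliest month and flagged, so peak
histograms are deterministic. Monthly climatologies average per calendar
month across years; unobserved months stay NaN rather than being
imputed.

## Landcover

Fraction grids (row-major, origin upper-left, square pixels, pixel
centers at (i+0.5, j+0.5)·cellsize) are thresholded **strictly above**
50% — a pixel at exactly 0.5 does not count — then member-pixel counts
convert to km². Distance-to-urban is straight-line between pixel
centers from the catchment outlet, undefined when no pixel passes the
threshold; published distances of this kind may be along-stream or road
distances, so this descriptor is not expected to be audit-reproducible.
Rasters travel as plain-text ESRI ASCII grids.

## Synthetic data: what it emulates, and what it does not

The generators (`floatload.synthetic`) are pure functions of a seeded
`ScenarioConfig`:

* **trait records** — lognormal scatter (rel. sd 0.3 by default) around
  configured true means, median-centred; positivity-preserving, like the
  wide spread of published trait values;
* **gauges** — log-uniform areas over 100–50,000 km², Q on a power law
  (a=0.01, b=0.9) with lognormal noise σ=0.2, 20 stations;
* **cover series** — monthly observations 1990–2019: a sharpened annual
  cosine (exponent 6) peaking in April, baseline 0.2 km², amplitude
  5 km², a 3-month post-flush collapse (×0.25 from June), multiplicative
  noise cv 0.1;
* **concentrations** — four quarterly samples (Mar/Jun/Sep/Dec) around
  seasonal means, cv 0.1, each sample carrying a configurable
  probability of a ×10 outlier (the outlier uniform is always drawn, so
  scenarios differing only in outlier probability share noise);
* **landcover** — rectangular blobs of fraction 0.8 on an empty grid
  with a rectangular catchment mask.

These reproduce the *statistical structure* the pipeline assumes —
positivity, power-law scaling, a dominant seasonal peak, rare outliers,
spatially clumped landcover. They do **not** emulate sensor gaps and
cloud-masking in real cover series, serially correlated hydrology,
mixed-pixel landcover boundaries, or covariance between biomass and
tissue content. Passing tests therefore validate the computations and
their invariants, not the field accuracy of any particular input.

The `zambezi_demo()` bundle is different in kind: it carries the
observed study inputs (discharges, peak vegetation areas, mean
concentrations, landcover areas) verbatim, so the full pipeline
regenerates the published pools, loads and sink fractions end to end.
The bundle keeps each catchment-area value as printed in its source
table even where two tables disagree by a few km².

## Numerical choices and degenerate inputs

* Aggregation default is the **mean**; the median is an explicit
  sensitivity switch (`aggregation="median"`), never silently applied.
* Zero vegetation area → zero pool with a degenerate (point) envelope;
  sink fraction 0%. Zero pool *and* zero load is an error, not a NaN.
* A single-study trait synthesis reports SE 0 with a `single_study`
  flag and a warning.
* Rating fits require ≥2 stations with distinct areas; noiseless fits
  recover (a, b) to machine precision.
* Internal computation is full precision; any rounding happens only at
  presentation.

## Problem sizes

The verification studies use 500 replicate gauge networks of 20
stations, 10⁵ Monte-Carlo draws for the envelope cross-check, 20–30-year
monthly cover series, and 20 replicate quarterly concentration series —
sizes at which the sampling error of each check is far below its
tolerance while the whole suite runs in seconds.

## Known limitations

* The trait defaults are calibrated stand-ins, not a re-synthesis of the
  literature; real applications should supply their own trait CSV.
* The envelope ignores biomass–content covariance (plants in richer
  water are both denser and more nutrient-rich), which would widen it.
* Trap efficiency below 100% biases the sink fraction low; nothing
  estimates how low.
* Landcover ratios inherit whatever georegistration the input grids
  have; no reprojection is performed.
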