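# Methods

This note documents the models, conventions, parameters and numerical
choices behind `treethreat`, and what the synthetic test worlds do and do
not establish about behaviour on real data.

## Occurrence quality control and minimal-area species

Occurrence records carry upstream quality codes from AAA (best) to H
(worst). The default allowlist {AAA, AA, A, B, C} keeps records whose only
issues are isolated coordinate *or* environment anomalies and drops records
with joint coordinate-and-environment problems, unknown ranges, duplicates
or missing coordinates. Exact coordinate duplicates per species (compared
after rounding to 6 decimal places, ~0.1 m) are collapsed; fuzzier
deduplication is assumed to have happened upstream.

Area of occupancy (AOO) is the Red List quantity: occupied 2×2 km cells ×
4 km². The 2-km tiling needs a projection the convention does not specify;
we use a world-anchored Lambert cylindrical equal-area mapping
(x = R·λ, y = R·sin φ, R = 6371.0088 km, origin at 0°/0°), which preserves
the km² semantics at every latitude. Species with n < 5 records (the hull
requirement), AOO < 10 km² (the Critically-Endangered occupancy bound,
strict comparisons in both cases per "less than"/"smaller than"), or a
degenerate hull cannot support grid-based rates; they bypass the rate
stages and are priority candidates by default. All records count toward
n; coincident records count once toward AOO.

## Refined extents

**MCP-95.** The convention of home-range MCP estimation is followed: the
`round(0.05·n)` records with the largest great-circle distance to the
arithmetic centroid of the coordinates are dropped (ties broken by record
order, earlier records kept), and the convex hull of the rest is the raw
extent. `inclusion=1.0` reduces to the full hull. Hulls that are lines or
points are flagged degenerate and the species excluded. Which 5% to drop
is a genuine convention choice; centroid distance is the one home-range
software implements, and it is what the removal of country-centroid-type
outliers calls for.

**Climatic suitability.** For every record, a disc of radius 1 km is laid
out in a local tangent plane (1/111.32° latitude, stretched by 1/cos φ in
longitude; at 1 km the planar approximation error is negligible). Grid
cells overlapping the disc by at least 25% of the disc's area are
collected over all records (distinct cells), and zones covering at least
5% of the collected cells are suitable. Both thresholds are inclusive
("at least"). Whether the 25% is of buffer or of cell area is ambiguous in
the source convention; we use the buffer area reading.

**Coverage weights and area.** Cells inside the polygon get
w = exact polygon∩cell area fraction (computed in degree space with exact
polygon clipping — the same quantity an exact-extraction zonal-statistics
tool returns), restricted to suitable, non-water cells. Geodesic cell
area is (πR/180 · res)² · cos(φ_center) km². Water is masked after zones;
the two masks commute (intersection), which a test asserts. Extents
crossing the antimeridian are rejected with an explicit error — a
documented limitation, irrelevant for the synthetic worlds. The analysis
grid is 0.01° in production use and coarser (0.05–0.25°) in tests; all
operations are resolution-parametric.

## Rates of recent change

Unidirectional conversion layers are preprocessed per their sources:
cropland expansion is the union of the four post-baseline epochs minus the
2000–03 baseline (16-year window); tree-cover decline marks any ≥5
percentage-point drop in a single consecutive comparison of the 2000, 2005,
2010, 2015 maps (15 years) — three 3-point drops in a row do *not* count;
built-up expansion is code 2 of the {0,1,2} classification (20 years);
deforestation is the binary loss map as-is (20 years). Window lengths are
stored as data and configurable. Rates are
`100 · changed coverage-weighted area / EOO_area / Y`, bounded in
[0, 100/Y] and exactly 100/Y at full conversion.

Bidirectional threats build a yearly series over the extent: burned area as
the coverage-weighted burned area (km²) per year; climate variables as the
coverage×area-weighted mean. The weighted mean (rather than an unweighted
cell average) is used because boundary cells should contribute in
proportion to how much of them the species' polygon actually covers. The
trend is the Siegel repeated-medians slope — per point the median of the
pairwise slopes to all other points, then the median over points — with a
50% breakdown point, so short environmental series survive gross single
years. The intercept is median(y − slope·x).

**Significance gate.** A rate is the slope only when the trend is
significant; otherwise it is set to exactly 0 (flagged, and the zeros
participate in the percentile thresholds). The gate is the two-sided
Mann–Kendall test (Kendall τ of value against year; exact null for short
untied series, tie-corrected normal approximation otherwise) at a single
global α = 0.05 for all bidirectional threats. The obvious alternative — a
signed-rank test on the per-point median slopes — is not a valid test:
those medians share the underlying pairwise slopes and are strongly
positively correlated, and simulation puts its null rejection rate above
0.3 at α = 0.05. Mann–Kendall is the standard companion of median-based
slope estimation and is calibrated (measured ≈ 0.04–0.05 under the null,
1,000-rep simulation in the test suite and acceptance script).

**Outliers.** Per threat, rates outside
[Q1% − 3·(Q99% − Q1%), Q99% + 3·(Q99% − Q1%)] are extreme even against the
tails; such species are dropped from the cross-status analysis (flagged,
counted separately in the manifest). The spread here is the 1–99
interpercentile range, tying the 3× multiplier to the quantiles that anchor
the rule.

**Imputation.** Minimal-area species receive neighbourhood rates: on a
1° grid, each cell's value per threat is the mean rate of the valued
species whose *records* fall in it (occurrence presence, not extent
overlap), and a minimal-area species gets the median over its occupied
cells. Imputed rates are flagged and excluded from threshold computation.

**Time windows.** Trend rates are window-parametric: recomputing climate
rates on 10-year halves of a stack with a constant planted slope returns
the same slope in both decades (asserted noiselessly exact in tests),
matching the decadal re-evaluation cycle the screening is meant to feed.

## Prioritization and hotspots

Thresholds are empirical type-7 (linear interpolation) quantiles at
q = 0.95 over all non-removed, non-imputed rates, zeros included; the
convention is recorded in the threshold output for reproducibility.
Comparison is strict (`>` upper, `<` lower); bidirectional threats flag
both tails, since both directions of change (e.g. fire loss as well as fire
gain) are ecological signals. With all-distinct rates the number of species
above the upper threshold is ⌊0.05·N⌋ or ⌈0.05·N⌉; at N = 32,090 that is
1,605 species per threat. A minimum of 20 valued species per threat is
required before thresholds are computed.

Hotspot layers rasterize extents to presence (any positive weight),
stack them into per-cell counts, and divide priority counts by the count
of all rate-assessed species (cells with none are masked). The six-threat
overlay binarizes each threat-category hotspot at presence — a single
priority species makes a cell part of that threat's layer — and sums, so
values run 0–6. The climate category aggregates its six variables by
"any variable flagged".

## Synthetic worlds

The generator partitions the analysis grid into one rectangular core block
per species and plants: a Gaussian occurrence cluster (default sd 0.15°,
30–80 records, clipped to the block so ranges stay disjoint and truth is
recoverable per species) with label frequencies skewed toward good
records; a Voronoi mosaic of `n_zones` climate zones; a random water mask
(default 5% wet); per-block changed-cell fractions for each conversion
threat (default U(0, 0.6); realized fraction recorded, within half a cell
of planted); per-block linear trends for each climate variable with iid
Gaussian noise (defaults scaled to observed per-extent decadal extremes:
order 0.1 °C/yr, a few Pa/yr, a few mm/yr; a Student-t option exercises
heavy tails); and a yearly burned-area indicator whose block burned
fraction follows a planted linear ramp. Status codes are drawn from
frequencies loosely matching the global tree flora (~13% Data Deficient,
~18% never evaluated, threatened minority). One seed expands into
independent per-component substreams, so identical configurations yield
bit-identical worlds.

What passing tests show: the estimators, masks, rates, thresholds and
accounting are implemented exactly as specified, and recover planted truth
under the stated noise models. What they do not show: behaviour under
spatially autocorrelated climate noise, non-convex or fragmented real
ranges, label errors correlated with location, or the real products'
native resolutions (30 m–250 m) — the generator works at the analysis
grid's resolution and does not emulate sensor-level preprocessing.

## Numerical choices and edge cases

- Cells are half-open [west, east) × [south, north); points on the outer
  north/east edge belong to the last cell.
- Coverage weights below 1e-12 are discarded; weights are clipped to 1
  against floating-point overshoot.
- Degenerate inputs raise typed errors (`MinimalAreaError`,
  `DegenerateHullError`, `UnusableZoneError`, `EmptyExtentError`) and the
  pipeline routes the species to the appropriate accounting category; the
  manifest identity *input = analyzed + minimal + degenerate + outlier*
  is asserted on every run.
- Repeated-medians is vectorized O(n²) and tested for exact equality
  against a loop-based enumeration oracle and an independent library
  implementation of the same estimator.
- All file formats are plain text (ESRI ASCII grids, CSV, GeoJSON, JSON);
  floats round-trip bit-exactly (repr on write, round-trip parsing on
  read), which is what makes whole-run bit-level determinism testable.
- Test problem sizes (50 species, 0.05–0.25° grids, 20-year stacks) keep
  the full suite and the acceptance script in the tens of seconds while
  exercising every code path; all sizes are parameters of the generator.

## Known limitations

- No antimeridian support; no true geodesic buffering (the 1-km disc is a
  tangent-plane approximation); spherical rather than ellipsoidal areas
  (< 0.3% relative error, immaterial for screening ratios).
- Exposure is not risk: rates measure change within the extent,
  independent of species' sensitivity or adaptive capacity, and
  overlapping threats (deforestation within expanding cropland) are
  counted in each layer.
- The 95th-percentile threshold is relative to the analyzed species set;
  with small synthetic worlds the per-threat candidate count is by
  construction ~5% of species per tail, and the union over eleven layers
  is correspondingly large.
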