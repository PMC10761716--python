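# treethreat

Data-driven threat-exposure screening for tree species.

Expert-based Red List assessment cannot keep pace with how fast threat
landscapes change: land conversion, fire regimes and climate shift within a
species' range on decadal timescales, while formal re-evaluations happen at
best every five to ten years. `treethreat` implements a screening pipeline
that quantifies, per species, the *rate of recent change* (RRC) of six
anthropogenic threat proxies inside a refined estimate of the species'
range, and uses the resulting exposure distribution to nominate species for
expert re-evaluation and to map hotspots of highly exposed floras.

## The method

**Refined extents.** A species' extent starts as the minimum convex polygon
of the 95% of its quality-controlled occurrence records nearest the
coordinate centroid (MCP-95). Climatically unsuitable zones — climate-zone
classes that cover less than 5% of the grid cells inside 1-km buffers
around the records — and water are masked out. Extent area is the exact
coverage-weighted sum

    EOO_area = Σ_cells w_c · A_c ,

where `w_c` is the fraction of cell `c` covered by the polygon and `A_c`
its geodesic area. Species with fewer than 5 records or an area of
occupancy below 10 km² (on a 2×2 km equal-area grid) are *minimal-area*
species: too small or too poorly sampled for grid-based rates, and
prioritized by default.

**Rates of recent change.** For unidirectional threats (cropland expansion,
tree-cover decline, built-up expansion, deforestation) the rate is the
converted area as a percentage of extent per year:

    Rate = 100 · Σ_{changed} w_c A_c / EOO_area / Y        [% extent yr⁻¹]

with `Y` the threat window (16, 15, 20, 20 years), so rates saturate at
`100/Y` (5.0 %/yr for a 20-year window). For bidirectional threats (burned
area; annual minimum/maximum temperature, VPD and its seasonality,
precipitation and its seasonality) a yearly series is aggregated over the
extent and a robust trend fitted by **Siegel repeated medians**,

    slope = median_i  median_{j≠i}  (y_j − y_i)/(x_j − x_i) ,

gated by a two-sided Mann–Kendall test: a significant slope is the rate
(burned area re-expressed as % of extent per year), a non-significant one
is exactly 0.

**Prioritization.** Per threat, species whose rate exceeds the empirical
95th percentile (or, for bidirectional threats, falls below the 5th) are
priority candidates; candidacy is cross-tabulated against Red List status
groups (Threatened / Vulnerable / Not Threatened / Data Deficient / Not
Evaluated), and candidate extents are stacked into per-cell hotspot counts,
fractions, and a six-threat overlay.

Because the real global inputs (occurrence corpora, decadal remote-sensing
products) are far beyond desk scale, the package ships a synthetic-data
module that generates miniature worlds with known planted truth — clustered
occurrences with quality labels, Voronoi climate-zone mosaics, binary
change layers with controlled changed fractions, annual stacks with planted
linear trends — so that every stage is testable against exact expectations.

## Worked example

```sh
treethreat run-all --seed 7 --n-species 50 --resolution 0.05 --out demo
```

prints

```
species: 50 in = 50 analyzed + 0 minimal + 0 degenerate + 0 outlier-removed; 32 priority candidates
```

i.e. all 50 generated species supported an extent and rate computation and
32 exceeded at least one per-threat exposure threshold. `demo/outputs/`
then holds, among others, `rrc.csv` (one rate per species × threat layer,
with significance/imputation flags), `thresholds.json` (e.g. upper
thresholds `cropland_expansion: 3.675`, `deforestation: 2.839` % extent/yr
for this world), `congruence.csv`:

```
group,n_species,n_candidates,pct_of_candidates,pct_of_group_candidate
Threatened,7,5,15.625,71.42857142857143
Vulnerable,7,4,12.5,57.142857142857146
Not Threatened,28,18,56.25,64.28571428571429
Data Deficient,3,2,6.25,66.66666666666667
Not Evaluated,5,3,9.375,60.0
```

(here 18 of the 32 candidates are currently listed as Not Threatened — the
kind of mismatch the screening is designed to surface), and hotspot maps
(`hotspot_*.asc`, `threat_overlay.asc`) as ESRI ASCII grids readable by any
GIS. Stage subcommands (`simulate`, `qc`, `extents`, `rrc`, `prioritize`,
`map`) operate on a shared workspace written by `simulate`.

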