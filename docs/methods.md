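# Methods

## Input model

The pipeline consumes a composite cumulative-pressure raster, not the eight
underlying pressure layers: an integer score 0–50 per cell, with nodata for
ocean and excluded regions (Antarctica and rock-and-ice areas are expected
to arrive as nodata, not as a special code). Continuous-valued rasters are
brought onto the integer scale by truncation toward zero
(`truncate_scores`), the convention used to derive the integer Human
Footprint from the continuous product; inputs outside [0, 51) are rejected
rather than clipped.

Areas are carried by the grid (`cell_area_km2`, uniform or per-cell), never
computed from geographic coordinates. Real-world use therefore presumes an
equal-area projection (the source data are on a Mollweide 1 km grid); for
ESRI ASCII inputs the cell area defaults to `(cellsize / 1000)²` km², i.e.
the header cellsize is read as metres.

## Contiguity

Blocks are maximal connected components of a boolean mask. The default
connectivity is 8 (diagonal neighbours are contiguous), matching the common
GIS region-group default; it is a parameter everywhere so 4-connectivity is
one flag away, because the original workflow's rule is not documented.
Labeling is delegated to `scipy.ndimage.label` and then renumbered into
row-major first-encounter order, making block identifiers deterministic and
independent of library internals. When a realm map is supplied, each realm
is labeled independently, so a block never straddles a realm boundary (the
Last of the Wild is defined per biorealm); the pressure-free map is labeled
without realm restriction.

Area filters are strict: a block of exactly 10,000 km² is excluded
(">10,000 km²" is read literally).

## Pressure-free lands

Wilderness per epoch is the set of components of {score = 0} with area
> `min_area_km2` (default 10,000 km²). Components are formed before the
size filter, so a large zero region bisected by a one-cell pressure line
becomes two blocks, each judged on its own area.

The 2009 map is made comparable with 1993 by intersecting the two zero
masks at cell level *before* labeling: a cell with pressure in 1993 and
none in 2009 is excluded, which can split or shrink 2009 blocks. That is
the intended behaviour — the exclusion operates on locations, not blocks —
and it guarantees the comparable map's cells are pressure free in both
epochs. Restoration (1993 > 0 → 2009 = 0) is deliberately not mapped.

## Last of the Wild

Per biorealm, the threshold is the minimal integer score whose cumulative
area reaches the target fraction (default 0.10) of realm land area:
`t_r = min { s : area(score ≤ s) ≥ 0.10 · area(r) }`. "At least 10%" on an
integer scale can overshoot substantially (a realm that is 35% pressure
free has t_r = 0 and captures 35%); the captured area is recorded per realm
for transparency. Thresholds are monotone in the fraction.

Selection per realm takes the within-realm components of {score ≤ t_r} and
retains the union of (i) the `top_k` = 10 largest by area, ties broken by
first-encounter block id, and (ii) every block > 10,000 km². The union is
order-independent and can retain more than ten blocks; whether the original
GIS workflow applied the two rules in sequence is unknown, so the
order-independent union is the documented choice.

The three variants share one code path: LoW_1993 scores the 1993 grid
against 1993 thresholds; LoW_2009_comparable scores the 2009 grid against
the *unchanged* 1993 table (asserted bit-identical in tests); LoW_2009_current
recomputes thresholds on the 2009 grid.

## Validation statistics

Mapped scores are normalised as score/50; the visual scale maximum is input
metadata defaulting to the same 0–50 key. Plots flagged uncertain are
dropped before score agreement (`filter_certain`); the map-intersection
checks take whatever plot set the caller supplies, since the published plot
counts for those checks do not restate the certainty criterion.

* **RMSE** on the normalised scale.
* **Banded kappa.** The published analysis pairs a "within 20%" match band
  with a categorical kappa without stating the categories. Here both score
  vectors are discretised into ⌈1/tolerance⌉ equal-width classes over
  [0, 1] (right-closed at 1) and unweighted Cohen's kappa is computed on
  the contingency table. The band test and the class test disagree near
  class edges, so the banded counts and the class-based kappa are reported
  side by side; kappa is flagged undefined (`None`) when chance agreement
  is 1. Because the original categorisation is unrecoverable, reproducing
  the published kappa from the archived workbooks is a validation exercise,
  not a guarantee.
* **Decomposition.** within = |Δ| ≤ tolerance (boundary inclusive, matching
  "up to 20% … as acceptable"); above/below by the sign of the excess; the
  three always sum to n.
* **Percentages** are rounded half-up to one decimal, the printed precision.
* **Map intersection.** A plot belongs to a block if its cell does
  (half-open pixel convention: a point on a boundary belongs to the cell
  right/below). Inside wilderness, strict agreement is a visual score of
  exactly 0; inside the Last of the Wild, a visual score at or below the
  plot's biorealm threshold t_r/50, with the tolerance-relaxed count
  alongside.

Reproducing the published real-data statistics (RMSE 0.125; kappa 0.737 at
the 20% band, 0.565 at 15%, 0.856 at 25%; the 88.5/88.1/98.9/86.9/98.7%
agreement figures) requires the archived global rasters and validation
workbooks; given those as CSV/ASCII exports, `score_agreement`,
`validate_wilderness_map` and `validate_low_map` compute the same
quantities. The repository's tests assert the arithmetic identities of the
printed counts and the behaviour of the statistics on synthetic data, not
the real-data values.

## Synthetic generator

The generator emulates the features the analysis depends on:

* **Autocorrelated scores.** White noise smoothed with a Gaussian kernel
  (σ = `smoothness` cells, wrap boundary) and rank-mapped monotonically onto
  the score distribution: the lowest `zero_fraction` of land cells become 0,
  the rest spread uniformly over 1..50. The realised zero fraction is exact
  up to rounding. Rank mapping keeps the spatial structure of the smoothed
  field while giving exact distribution control.
* **Epoch evolution.** Per cell: +1..+5 capped at 50 with probability
  `increase_rate`, else −1..−score floored at 0 with probability
  `decrease_rate`, else unchanged. Decreases exist specifically so the
  temporal-comparability exclusion has cells to exclude.
* **Realms.** Nearest-seed (Voronoi) tessellation of the land cells from
  uniformly sampled seed cells, ties to the lowest id — contiguous,
  non-empty, deterministic.
* **Plots.** Uniform sampling of land cells without replacement; the visual
  score is the true normalised score plus N(0, `plot_noise_sd`), clamped to
  [0, 1]; certainty is Bernoulli. Uniform sampling is a stand-in: the
  spatial stratification of the real validation plots is not documented.

All randomness derives from one root seed through named substreams
(grid / evolution / partition / plots / nodata), so generating more plots
never perturbs the rasters, and identical configs are bit-identical.

What the generator does *not* emulate: coastline geometry,
latitude-dependent cell area, the eight individual pressure layers, spatial
clustering of score changes, or any correlation between plot certainty and
imagery quality. Passing tests therefore demonstrate correctness of the
mapping and statistics machinery, not performance of the Human Footprint on
real landscapes.

## Problem sizes and defaults

The end-to-end study system used by the tests and `scripts/acceptance.py`
is a 128×128 grid of 100 km² cells (1.64 M km² of land), six realms,
`zero_fraction` 0.35, `smoothness` 6 cells, `increase_rate` 0.15,
`decrease_rate` 0.02, 500 plots with noise sd 0.05 and 90% certain — large
enough that multiple blocks clear the 10,000 km² filter in every realm
while the whole pipeline runs in seconds. Unit and oracle tests use 4×4 to
64×64 grids. Numerical details: cumulative-area comparisons use a 10⁻⁹ km²
slack against float accumulation; kappa's degenerate case (p_e = 1) returns
`None` rather than NaN; percent uses decimal half-up rounding, not binary
float rounding.

## Known limitations

* No geodesic areas and no reprojection; garbage in (a non-equal-area grid)
  gives garbage areas out.
* Shapefile output is not written; GeoJSON is the single vector dialect
  (lossless attribute names, one file per product).
* The banded-kappa categorisation and the 8-connectivity default are
  documented choices where the original workflow is silent; both are
  parameters.
* Excel workbooks are not parsed; export validation tables to CSV first.
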