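# Methods

This note documents the models, conventions, and numerical choices behind
`suitmap`, and what the synthetic experiments do and do not demonstrate.

## Grid and geodesy

All layers live on one regular geographic (WGS-84) grid of square `res`°
cells, row 0 northmost. Cell (i, j) covers latitudes
`[origin_lat − (i+1)·res, origin_lat − i·res)` and longitudes
`[origin_lon + j·res, origin_lon + (j+1)·res)`: half-open intervals, south
and west edges inclusive. A point on a shared edge therefore belongs to
exactly one cell; duplicate coordinates collapse to one presence cell. These
conventions are declared, not canonical — other GIS stacks choose
differently — and the tests pin them.

Cell areas use a spherical Earth of authalic radius R = 6371.0072 km with
the band formula `A = R²·Δλ·(sin φ_top − sin φ_bot)`, which is exact on the
sphere; the areas of any full global grid sum to 4πR² to machine precision
(tested at 1° and 0.5°, relative error < 1e−10). Areas are accumulated
unrounded and rounded to 2 decimals only at report time, so percentage
columns can disagree with recomputation from the rounded cells by up to the
printed precision. 1 Mha = 10⁴ km².

The "5 km" cell size quoted for such analyses is the 0.05° cell near the
equator; no equal-area regrid is performed — the analysis grid is the
accounting grid.

Slope is the Horn 3×3 stencil on elevation, in degrees, with the
metres-per-degree of longitude scaled by cos(latitude); cells without a
fully valid 3×3 neighbourhood (including the grid edge) are nodata.

## Raster interchange

Rasters are single-band GeoTIFFs with explicit nodata, carried by the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory declaring geographic WGS-84, and GDAL's ASCII nodata tag),
written and read through `tifffile`. Only axis-aligned square-cell
georeferencing is supported; a ModelTransformation (rotation) or missing
tags is a format error. Integer rasters round-trip bit-exactly.
Occurrence points are CSV with `lat`/`lon` columns (the longhand
`latitude`/`longitude` spellings are accepted); rows with missing or
out-of-range coordinates are dropped and counted.

## Background sampling

Background candidates are all valid cells whose *reference* suitability is
strictly below 0.5; cells exactly at 0.5 are excluded (the suitability
threshold on the other side is inclusive, so the two rules partition
[0, 1]). Presence cells are excluded from candidacy even when the reference
scores them unsuitable. Each of the B draws samples `|presences|` candidate
cells uniformly without replacement, seeded `base_seed + b`, so draw
families are reproducible and enumerable; cells may recur across draws.

When no external reference surface is supplied, a single bootstrap
sub-model (fit against a uniformly random equal-count background, including
CV tree selection) provides the screening reference. An externally supplied
reference raster takes priority and bypasses the bootstrap.

## Boosting

Sub-models are stagewise additive logistic boosting with Bernoulli
deviance: depth-≤`tree_complexity` regression trees fit to the negative
gradient on a `bag_fraction` random subsample, scaled by `learning_rate`;
the intercept is the log-odds of training prevalence. LightGBM is the
engine (single-threaded, deterministic mode); every contract control maps
directly onto it (`max_depth`/`num_leaves`, `bagging_fraction` with
`bagging_freq=1`, `learning_rate`, `seed`). Defaults follow established
ecological-BRT practice: learning_rate 0.005, tree_complexity 4,
bag_fraction 0.75, minimum 10 observations per leaf, ten stratified CV
folds, tree search in steps of 50 up to max_trees.

Tree-count selection records the held-out deviance (2× mean negative
log-likelihood) of each fold at every iteration and picks the step count
minimizing the fold mean; ties break toward fewer trees (parsimony), and a
minimum at the boundary emits a warning rather than an error. Per-fold
held-out AUC at the selected count is retained, and the ensemble reports
mean ± SD both across all folds and across sub-model means, since either
axis is a defensible "CV AUC".

Training is a pure function of the row *set*: rows are sorted
lexicographically over (features, label) before any seeded operation, so
shuffling the input leaves the fitted model bit-identical. Soil class is a
native categorical split variable (no one-hot expansion); soil depth and
slope are continuous.

Relative contribution credits each split's objective-gain to its split
variable, accumulated over all trees and normalized to 100%. The ensemble
table reports the mean across the B sub-models with a normal-approximation
95% CI (mean ± 1.96·SD/√B); a percentile CI is available as an option.
Marginal effect curves are clamp-and-average partial dependence on the
probability scale: the evaluation grid spans the training 1st–99th
percentiles, and the response at each grid value is the mean prediction
over the (sub-model's) training table with the variable clamped there;
ensemble curves average sub-model curves pointwise on a shared grid pooled
across training tables. Partial dependence is defined for continuous
variables; categorical effects should be tabulated per class instead.

The ensemble map is the per-cell arithmetic mean of the B sub-model maps;
uncertainty is the per-cell population standard deviation (ddof = 0).

## Accounting

A cell is suitable iff ensemble mean suitability ≥ τ (default 0.5),
thresholding the *ensemble mean* map rather than voting per sub-model.
Marginal land is the intersection with an allowed land-cover class set,
default the shrubland/savanna/grassland range (IGBP-style codes 6–10),
fully configurable. Region areas are sums of exact band areas over masked
cells; an empty mask reports zero areas with an explicit flag rather than
undefined percentages. Scenario deltas satisfy, exactly and by
construction: net = expansion − contraction, net(A→B) = −net(B→A), and
expansion(A→B) = contraction(B→A). Future projections reuse current
topography and soil with shifted climate layers.

## The synthetic world

The generator emulates the statistical structure the analysis assumes:

* **Covariates** — smoothed Gaussian random fields (σ ≈ min(n)/33 cells)
  mixed with a north–south trend, giving strong positive spatial
  autocorrelation; a shared "ocean" nodata mask (~10% of cells); an
  elevation field with derived slope; six soil classes from a thresholded
  smooth field. Layer locations/scales are set to plausible bioclim-like
  ranges (e.g. temperature annual range ≈ N(34, 8) °C).
* **Truth** — logistic over additive responses. The default niche puts 75%
  of the total effect weight on a window response of the temperature annual
  range (suitable roughly below 30 °C, collapsing above it), with minor
  saturating effects of wettest-quarter precipitation and coldest-quarter
  temperature: a strongly temperature-limited tropical crop. With the
  default world this yields ~28% of the landscape suitable.
* **Occurrences** — cells drawn with probability proportional to truth
  suitability (exponent 1; the simplest observation model consistent with
  "occurrences reflect suitable conditions"), jittered uniformly within the
  cell, duplicates allowed. The default 1600 points collapse to ≈1480
  presence cells on the 200×200 world.
* **Scenarios** — additive per-layer climate offsets growing with pathway
  forcing and horizon; topography and soil untouched. In the default world
  warming raises the temperature annual range toward and past the window's
  upper edge, so suitable area *contracts* — the direction the truth
  implies, which the tests exploit.

What passing recovery tests show: the pipeline can recover a known,
strongly dominated, low-dimensional niche from clean presence-only data on
an autocorrelated landscape. What they do not show: robustness to sampling
bias, collinear 19-layer bioclim stacks, label noise, regional truncation
of niches, or observation models other than proportional sampling — real
occurrence data have all of these.

## Problem sizes for the replicated experiments

The full recovery experiment uses the default world (200×200, B = 25,
max_trees 1000 at learning rate 0.005 — the cap keeps a complete run in the
minutes range; the CV minimum typically sits at the cap, which the selector
reports as a warning). The replicated dominance check — is the dominant
generative variable ranked first? — runs 20 seeds at reduced scale (80×80
world, 400 points, B = 3, 150 trees at learning rate 0.05): rank recovery
of a 75%-weight effect is insensitive to ensemble size, so the reduced runs
measure the same property at a fraction of the cost.

## Known limitations

* Percentage columns of rounded tables can sum to 100 ± 0.05.
* GeoTIFF support is deliberately minimal (single band, axis-aligned,
  geographic); no reprojection.
* LightGBM's histogram splitter bins features (255 bins); split thresholds
  are bin edges, not exact sample midpoints as in exhaustive-search BRT
  implementations. At these data sizes the fitted functions agree with
  exhaustive boosting to well within ensemble variability.
* The bootstrap screening reference is fit from the same occurrence data it
  screens for; with an informative external reference surface, screening is
  closer to the published protocol.
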