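# Methods

`rangeshift` implements a complete climate-change range-projection analysis
for a species assemblage: bioclimatic covariates are derived from monthly
climate surfaces, maximum-entropy presence-background models are fitted per
species, projected across an ensemble of circulation-model realizations for
each decade, constrained by dispersal scenarios, and summarized as
per-species range change and assemblage richness. Everything runs on
synthetic climate and virtual species, so each stage can be checked against
known ground truth.

## Grids and units

All rasters share one rectangular grid of square cells whose size is given
in kilometres (default 5 km, the working resolution of continental-scale
atlas analyses at ~0.05°). Distances and areas are plain Euclidean
quantities; nodata is NaN. Keeping the grid metric avoids geodesy entirely;
geographic inputs would be converted via a mean cell size before entering
the pipeline.

## Bioclimatic covariates

Six covariates drive the models: annual mean temperature (`mat`, °C),
temperature seasonality (`ts`, the population standard deviation of the
monthly means as a percentage of the annual mean), maximum temperature of
the warmest period (`twp`, °C), annual precipitation (`ap`, mm),
precipitation seasonality (`ps`, %), and precipitation of the driest period
(`pdp`, mm). A "period" is a calendar month, because the inputs are monthly
surfaces. Percent-of-mean seasonality is undefined where the annual mean
temperature is not positive; such cells become nodata with a warning. A
`ts_convention="sd_x100"` switch provides the alternative convention (plain
standard deviation × 100) for parity with other bioclim toolchains.
Decadal climate labels are taken as window averages of yearly series; the
window is closed and symmetric with a configurable half-width, since the
asymmetric label mapping sometimes used in the literature (e.g. "1990" for
1985–2005) cannot be reproduced symmetrically and the choice does not affect
the synthetic pipeline, whose generator emits decade means directly.

## The maximum-entropy model

For each species the model is the Gibbs distribution over background cells
maximizing the L1-penalized log-likelihood of the presence sample

    l(λ) = mean_presences λ·f(x) − log Z(λ) − Σ_j β_j |λ_j|,
    Z(λ) = Σ_background exp(λ·f(x)),

with features f the linear, quadratic and pairwise-product terms of the six
covariates (27 features), min–max normalized on the background sample and
clamped to the training [0, 1] range at prediction time. Presences are
deduplicated to one per cell and added to the background sum (the standard
presence-background construction). The background is a uniform sample of
landscape cells (default 10,000; when the landscape is smaller, every cell).

**Regularization.** Penalties follow β_j = β_multiplier · sd_j(background) /
√m with m the presence count. The default multiplier is 0.001 — deliberately
weak. At this package's working scale (a few thousand background cells,
~200 presence cells, Gaussian niches a small fraction of each variable's
landscape range), a quadratic response requires large, partially cancelling
linear and quadratic coefficients in min–max feature units, and the moment
slack that an L1 penalty permits then translates into a variance bias of the
fitted niche that can exceed the niche variance itself: at multiplier 1.0
the penalized optimum is essentially the uniform distribution, and even at
0.05 (the scale of the original Maxent software's default for this feature
class at large sample sizes) the fitted niche breadth is inflated by a
factor of ~2. The default keeps that bias negligible while retaining the
penalty's role of suppressing uninformative features; for larger, noisier
real-world datasets the multiplier is the first parameter to raise.

**Optimization.** The objective is concave with a unique optimal value. The
positive/negative split of λ is solved by L-BFGS-B with a continuation
schedule (multiplier 0.5 → 0.1 → target), then polished by a proximal-Newton
loop whose L1 subproblem is solved exactly by cyclic coordinate descent (the
glmnet/QUIC construction) — first-order methods alone stall in the flat,
ill-conditioned valley that weak penalties create. Features that are
(near-)constant on the background or near-duplicates of another feature
(|correlation| > 0.999 — e.g. a product with a variable that barely varies)
are pruned before fitting; their coefficients are zero. The returned optimum
satisfies the KKT conditions of the penalized problem for every active
feature; convergence is declared on the minimum-norm subgradient or on
objective stagnation.

**Outputs.** The raw output is the Gibbs probability relative to the
background partition sum (summing to 1 over the background); the logistic
output is e^H·raw / (1 + e^H·raw) with H the entropy of the fitted raw
distribution, a monotone rescaling to (0, 1) whose value is 0.5 for a cell
of "typical" suitability. Models are evaluated by training AUC (presence vs
background, Mann–Whitney with ties counted half) and screened at AUC < 0.7;
screened species are excluded from species-level summaries but kept in
richness stacks.

**Binarization.** The species-specific threshold equates the entropy of the
thresholded and fitted distributions: keep the k highest-suitability cells
of the baseline landscape, where k minimizes |log k − H| (the size of the
uniform distribution with the fitted entropy), and return the k-th largest
logistic value. The threshold is computed once on the baseline prediction
and reused for every future projection.

## Ensemble projection

Each model is projected onto every (GCM, realization, decade) climate
surface. Per decade the ensemble mean is realization-weighted: cellwise mean
within each GCM first, then an unweighted mean across GCM means, so a model
with many realizations carries no extra weight. Extremes are unweighted
cellwise minima and maxima (weighting-invariant). Ensemble summaries stay on
the continuous suitability scale; binarization happens downstream on the
mean map. Whether to binarize each realization before averaging is a
genuine modelling fork; mean-then-threshold was chosen because the threshold
is defined against the baseline entropy and a single ensemble surface.
Climate-change maps difference temperature variables (future mean −
baseline) and ratio rainfall variables (future mean / baseline, nodata where
the baseline is zero), using the same two-stage mean.

## Dispersal scenarios

The current *potential* range (thresholded baseline suitability) is clipped
to subregions holding at least one occurrence record to give the current
*realized* range. Future ranges are limited by scenario:

* **full** — the future potential range, unclipped;
* **rate_limited** — intersection with a buffer around the current realized
  range growing by rate × 10 km per decade (default 3 km/yr, i.e. 30 km per
  decade). Buffers are anchored on the current range (not grown iteratively)
  and use exact Euclidean distance between cell centers; a cell is inside
  when its center is within the radius. For a decade list of length D the
  mask set has D nested masks; the i-th projected decade uses mask i, so
  ten decades give radii 30, 60, …, 300 km;
* **none** — intersection with the current realized range at cell level
  (a region-level variant, constraining only to the occupied subregions, is
  available as `none_level="region"`).

A per-species **realistic** scenario selects, for each species, the output
of the scenario named in its metadata; the assignment is input data, not
computed. Nesting none ⊆ rate-limited ⊆ full holds cellwise by
construction.

## Summaries

Range statistics are ClassStat-style landscape metrics of a binary range:
total area, patch count (connected components, queen's-case connectivity by
default, rook's case available), proportion of landscape, mean patch area,
and edge length (presence-cell edges adjacent to absence, nodata or the
grid border, times the cell size). Proportional change is the final-decade
area over the current realized area, rounded to two decimals before being
classified as Increase (> 1), Decrease (< 1) or No change (= 1), so a ratio
printed as 1.00 reads "No change". Assemblage summaries count and average
these classes. Richness maps stack the binary ranges of all species —
including AUC-screened ones, since per-species accuracy matters less for a
coarse assemblage count; the shared 1990 baseline stack uses the current
realized ranges, which also guarantees that no-dispersal richness change is
nowhere positive. Group comparisons are one-way fixed-effects ANOVAs of
proportional change across movement classes or biogeographic groups (groups
with fewer than two species are dropped with a warning); no multiple-testing
correction is applied to the two tests.

## The synthetic scenario

The bundled scenario is a deliberately scaled-down continent: a 60 × 80 grid
of 5-km cells (300 × 400 km) with temperature increasing northward at
30 °C / 1000 km — steep, so the grid's 9 °C span can absorb a full warming
trajectory — a wet season (December–March) carrying 90% of annual rainfall,
rainfall increasing eastward, and iid monthly noise of 0.3 °C. Four
circulation models with (1, 2, 3, 2) realizations and per-decade trends of
0.30–0.45 °C (realization-weighted mean ≈ +3.4 °C by 2080) and rainfall
factors within ±1% per decade project ten decades, 1990–2080. A Voronoi
mosaic of 12 contiguous subregions stands in for biogeographic regions.

Twelve virtual species have Gaussian niches over the six covariates,
anchored at interior grid cells (edge-truncated niches would break the
correspondence between a niche's entropy and its range size). Only `mat`
(width 0.6 °C) and `ap` (85 mm) constrain effectively; the other four widths
are large. Each species' true range is defined by the entropy-equating rule
applied to its true suitability surface, the same rule the pipeline applies
to fitted models — a numeric prevalence cutoff is also supported.
Occurrences are 230 presence-only draws per species, with replacement,
proportional to true suitability; model fitting deduplicates them and uses
at most 200 unique presence cells. The sampling intensity matters: drawing
many times more records than the niche holds cells saturates deduplication
and flattens the presence-cell distribution toward uniform-over-range, which
inflates the fitted entropy. Dispersal categories are 8 full / 3
rate-limited (3 km/yr) / 1 none; movement classes and biogeographic groups
cycle through the five values of each.

**What the generator does not emulate.** Real atlas data carry strong
spatial observer bias (the sampler accepts a bias raster, but the bundled
scenario uses none), spatially autocorrelated climate noise, topography,
coastlines and true geographic coordinates; niches are exactly Gaussian and
within the model's feature family. Passing tests therefore demonstrate that
the machinery is correct and self-consistent — parameter recovery on data
satisfying the model's assumptions — not that the method is robust to the
violations real data bring.

## Problem sizes and runtime

The default scenario (12 species × 8 realizations × 10 decades on a 4,800-
cell grid) runs the full pipeline in well under a minute on one CPU; the
test suite, including a complete pipeline run and all oracle comparisons,
takes about half a minute. Stage outputs are cached by a configuration hash
chained across stages, so re-running an unchanged configuration recomputes
nothing, and the expensive stages (fitting, the 80-surface projection) are
skipped whenever only downstream settings change.

## Known limitations

* Training AUC only; no held-out evaluation or cross-validation.
* The feature family omits hinge and threshold features, so sharply
  truncated responses are represented only through quadratic tails.
* Feature clamping at the training range means novel climates beyond it are
  scored at the boundary value — ranges can be retained in climates hotter
  than anything observed (visible in the bundled scenario as area inflation
  for the hottest-anchored species).
* The dispersal buffer is purely geometric: no landscape resistance,
  habitat-mediated lags, or mechanistic kernels.
* Fragmentation metrics are the minimal defensible set (patch count, mean
  patch area, edge length); richer landscape-metric suites are out of scope.
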