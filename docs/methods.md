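# Methods

## Scope and model

`riverscape` implements a riverscape habitat-suitability workflow on stream
*reaches*: short vector segments of a river network extracted from a DEM,
each carrying topographic and upstream-environmental covariates. Habitat
models are presence-background maximum-entropy density estimates — the model
family used for species distribution modelling when only occurrence records
(no absences) exist — and the downstream product is a binary suitable /
unsuitable classification per reach, from which suitable stream length and
between-species overlap statistics are computed.

## Hydrology

**Depression filling** is boundary-seeded priority-flood: valid cells on the
grid edge (or adjacent to nodata, which is treated as a drain) seed a
min-heap; cells are closed in order of increasing spill elevation and raised
to the spill level when below it. The fill is epsilon-free, so closed basins
become exact flats. Complexity O(n log n); cells outside depressions are
returned bit-identical.

**D8 routing** sends each cell to the neighbour with the steepest positive
drop per unit distance (diagonals √2 longer). Two conventions are fixed for
determinism: ties take the first neighbour in clockwise order starting at
East, and boundary cells with no downhill in-grid neighbour drain off-grid
(OUTLET). Flats remaining after filling are resolved by a breadth-first pass
seeded at cells of the flat that already drain (its spill); each flat cell
points to the neighbour it was reached from, which yields an acyclic gradient
across the flat by construction. An interior flat with no spill is an error
naming the region — it cannot occur on priority-flood output but can on
arbitrary user input.

**Accumulation** counts each cell itself plus all cells draining through it
(one pass in topological order; a cycle raises). Contributing area is
`count × cellsize²`, so the headwater rule "a stream needs at least
2.0 km² of catchment" is a direct threshold on area. The stream mask is
automatically closed downstream because accumulation is non-decreasing along
flow paths.

## Network extraction

Stream cells are traced cell-center to cell-center into segments running
from sources/confluences to the next confluence or outlet, then each segment
is cut from its upstream end into reaches of the grain length (default
1.0 km — an intermediate scale at which stream fish carry out their life
histories). A terminal remainder ≥ 1% of the grain becomes its own reach;
smaller slivers merge into the preceding reach, so confluence nodes are
preserved exactly and zero-length reaches cannot arise. Strahler order is
assigned over the reach DAG: sources are order 1; a confluence outflow takes
the maximum inflow order, +1 when two or more inflows share it; chain
reaches inherit.

A reach ending at a confluence stores the last cell *before* the junction as
its outlet cell, so its catchment does not absorb the sibling tributary;
catchment containment is therefore monotone downstream.

## Reach attributes

Local descriptors: gradient = 100 × (endpoint drop)/length (negative values
are DEM noise and clamp to 0 with a warning); sinuosity = path length /
endpoint chord. Catchment summaries (confluence density in nodes/km², stream
density in km/km², mean upstream slope — Horn 3×3, reported in degrees×100 —
and upstream means of environmental rasters) are all computed as weighted
flow accumulations in one topological pass each, O(grid) regardless of reach
count; per-reach flood-fill versions exist and are used as oracles in the
tests. Densities use the upstream catchment as their support area, the only
per-reach area the workflow defines.

Collinearity is handled by a greedy filter: scanning candidates in a
priority order (hydroclimate before topography before landcover before
soil, by convention), a variable is kept iff |Pearson r| with every kept
variable is < 0.7; constant columns are dropped first. The output is a
deterministic function of the data and the priority list.

## Maximum-entropy model

Predictors are min–max normalized on the *background* sample, then expanded
into feature classes: linear, quadratic, pairwise products, hinge (forward
`max(0,(s−k)/(1−k))` and reverse ramps at 50 evenly spaced knots by
default), and step thresholds. Transfer values are clamped to the training
range, the cited engine's default behaviour. Feature classes default by
presence count (`l` < 10, `lq` < 15, `lqh` < 80, else `lqph`), overridable.

The model is the Gibbs distribution over the background,
`q(x) = exp(βᵀf(x))/Z`, fitted by maximizing the penalized log-likelihood

    (1/n) Σᵢ βᵀf(xᵢ) − log Z(β) − m Σⱼ λⱼ |βⱼ|

where the per-feature weights λⱼ follow the published MaxEnt defaults: a
class- and sample-size-interpolated base (linear/quadratic/product:
1.0→0.05 as n goes 10→100; hinge 0.5; threshold 2.0→1.0) times the
feature's presence standard deviation over √n, floored at 1/√n for
near-constant features. `m` is the user-facing regularization multiplier.
The optimizer is cyclic coordinate descent with proximal Newton steps
(gradient `E_background[fⱼ] − mean_presence[fⱼ]`, curvature `Var_q[fⱼ]`,
soft-thresholded at λⱼ), the background linear predictor updated
incrementally; convergence is declared when every KKT residual is below
`tol` (1e-8 default), and non-convergence raises carrying the last residual.
The objective is convex, so the optimum is unique; the tests verify
agreement with an independent generic convex optimizer (scipy L-BFGS-B on
the split-coefficient reformulation) to 1e-4 in coefficient space.

Raw output `exp(βᵀf − log Z)` sums to 1 over the training background; the
display scale is cloglog, `1 − exp(−e^H · raw)` with `H` the entropy of the
fitted background distribution — strictly increasing in raw, so rankings are
scale-invariant. A logistic-style reading of the response is available via
`response_curve`, which returns marginal suitability along one predictor
with the others at their means (the qualitative "Gaussian response" check;
no pass/fail statistic is defined for it).

## Candidate evaluation and selection

Candidates form a grid of multiplier × feature-class string. For each:
AICc and the parameter count (non-zero β) come from the full-data fit, with
`AICc = −2LL + 2k + 2k(k+1)/(n−k−1)` and LL evaluated at the presences under
the background-normalized density; partial ROC and omission rate are
averaged over seeded k-fold cross-validation (default 10 folds; folds scoring
fewer than 10 presences are pooled instead). Omission uses the fold-model's
minimum-training-presence threshold on the cloglog scale.

Partial ROC restricts the ROC curve (x = share of background predicted
suitable, y = sensitivity) to the low-omission region y ≥ 1−E (E = 0.05 by
default) and reports the ratio of the model's partial area to the random
expectation (the diagonal's area over the same x-range); 1.0 is random,
values near 2.0 (the maximum at small E) indicate strong discrimination.
Significance is bootstrap-based: each of 500 replicates resamples 50% of the
test presences with replacement; p is the share of replicate ratios ≤ 1.
Numerical details: step curves over all unique score thresholds, linear
interpolation of the crossing at y = 1−E, trapezoidal integration; an
all-identical score vector yields ratio 1.0 with a warning.

Two calibration properties of this estimator are worth stating. The
empirical ratio is biased above 1 when the resampled presence count m cannot
resolve the sensitivity band (m·E ≲ 1: with m = 13 and E = 0.05 the only
attainable sensitivity ≥ 0.95 is 1.0, which sits above the diagonal by
construction). The bias decays as m grows; the test suite therefore checks
null calibration (ratio centred on 1, p ≥ 0.05 in ≥ 90% of runs) at test
sizes where m·E ≫ 1, and treats small-sample ratios as a ranking statistic
rather than a calibrated test — consistent with how the measure is used in
the model-selection literature.

Selection filters to significant candidates (p < α = 0.05), then to
omission ≤ E, then takes minimum AICc, ties broken by fewer parameters then
lower multiplier. If nothing passes the omission cut, the significant
candidate with minimal omission is selected and flagged; no significant
candidate at all is an error.

## Thresholds and overlap

MTP is the minimum cloglog suitability over training presences (zero
training omission by definition); P10 is the ⌈0.1·n⌉-th smallest training
score (training omission ≤ 10% plus the tie allowance; at n = 255 the 26th
smallest, omission ≤ 25/255 ≈ 9.8%). Ties at the threshold are suitable, so
P10-suitable reaches always nest within MTP-suitable ones. MTP is
appropriate for well-curated occurrence sets; P10 tolerates a 10% share of
dubious records (e.g. aggregated museum/GBIF data).

Overlap between a native and an introduced species is the share of
native-suitable reaches also suitable for the invader (asymmetric by
design), reported both as reach counts and as km totals; a union variant
uses "suitable for at least one invader". Reach elevation is the DEM value
at the polyline midpoint vertex; elevation distributions across suitable
reach sets are compared with Kruskal–Wallis (≥ 3 groups) and
Mann–Whitney/Wilcoxon rank-sum (pairs) from scipy.stats — the one place a
standard statistical routine is called rather than implemented; its formula
is still hand-checked once in the tests.

## Synthetic data

The generator provides the study conditions for all tests, so what it does
and does not emulate matters:

* **Terrain.** `tilted_plane` (noise-free, depression-free — filling is an
  identity), `valley_v` (cross-valley gradient dominating seeded smooth
  noise, one main stem), and `dendritic_fractal` (smoothed white noise at
  three scales, weights 0.15/0.35/0.5 at σ = 2/8/32 cells, on an eastward
  regional tilt) — drainable terrains with realistic branching, not replicas
  of any real range's hypsometry.
* **Environment.** Gaussian-smoothed random fields (σ = extent/10) scaled to
  name-appropriate ranges; "temperature" follows a 6.5 °C/km lapse on
  elevation plus weak local variation, giving the strong negative
  elevation–temperature correlation typical of mountain climates.
  Seasonality-style derived variables are treated as generic smooth rasters.
* **Virtual species.** True suitability is logistic in standardized reach
  predictors (linear + quadratic terms), with the intercept solved so mean
  suitability equals the prevalence target (0.3 default); presences are
  drawn without replacement with probability proportional to suitability,
  keeping prevalence continuous and recovery power tunable. Positional
  uncertainties are drawn in [5, 95] m so cleaning retains them. The default
  recovery species is a cold-water stream fish archetype: a thermal optimum
  (positive linear + negative quadratic upstream-temperature response) plus
  avoidance of steep reaches — ecologically natural and identifiable, since
  reach gradient varies at the reach scale while climate fields are smooth.

Passing recovery tests on these data show the estimator recovers a known
suitability ranking under correctly specified, moderately collinear
covariates on a realistic network geometry. They do not show robustness to
covariate measurement error, sampling bias in occurrences, spatial
autocorrelation of residuals, or model misspecification — all present in
real occurrence data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which each property is meaningful: hydrology oracles on ≤ 20×20
random grids (25 seeds); the modelling landscape at 256×256 cells of 50 m
(≈ 750 reaches at 0.2 km² / 0.5 km grain); the recovery landscape at
512×512 (≥ 10,000 reaches at 0.05 km² / 0.25 km grain, 200 presences,
10,000 background reaches, 5 species seeds). Fitter tolerance 1e-8 (KKT),
Newton steps capped at ±5 per coordinate; raw normalization holds to 1e-8;
reach-length conservation to 1e-6 relative. All randomness flows through
explicit integer seeds recorded in model metadata and the run manifest; two
runs with the same config and seed produce byte-identical CSV/JSON outputs.

## Known limitations

* Single-direction D8 only: no D-infinity or multiple-flow-direction
  routing, no braided or looped channels, no lakes; geographic (degree) CRS
  grids are out of scope — inputs must be projected with square cells.
* Rasters must be co-registered with the DEM; there is no resampling.
* The occurrence buffer radius and background size have no data-driven
  default (10 km / 10,000 here); both materially shape the background
  sample and should be set per study.
* AICc on presence-background likelihoods is a relative complexity measure,
  not an absolute goodness-of-fit.
* The bootstrap pROC p-value is anti-conservative at small test-presence
  counts (see above).
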