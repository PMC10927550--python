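# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `alpshift`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic study system

`synthetic.build_landscape` generates a planar metric grid (default
120×120 cells of 100 m; coarse factor 10, i.e. a 12×12 km toy massif
analysed at 1 km resolution) with:

- **Elevation**: a smooth Gaussian random field rescaled to
  [0, `relief_amplitude`] m (default 3000 m).
- **Climate**: growing degree days (GDD) load negatively on elevation
  (loading −√0.55) and annual precipitation (BIO12) positively (√0.30),
  each mixed with an independent smooth field; temperature (BIO4) and
  precipitation seasonality (BIO15) are independent smooth fields. Two
  soil proxies (plant-indicator nitrogen and calcareous substrate share)
  are independent smooth fields. Loadings were chosen so all pairwise
  Pearson correlations among the six continuous predictors fall below
  |r| = 0.7 — the screen is verified on every emitted stack, and the
  noise is regenerated (bounded retries) if a draw violates it.
- **Land cover**: six classes (grassland, forest, built-up, cropland,
  permanent crops, others) from an elevation + noise score, with built-up
  pinned near the synthetic cities; a second 10-class layer is derived by
  a fixed reclassification (grassland → pasture/semi-natural by
  elevation; cropland → irrigated/non-irrigated by precipitation), so
  that fitting "one model per categorical land-cover variant" is
  exercised.
- **PA network**: the top `pa_fraction` (default 0.18) of an
  elevation-plus-smooth-noise score — protected areas are deliberately
  biased upslope, as real mountain networks are.
- **Countries**: ≥3 contiguous Voronoi regions of random centres.
- **Roads/cities**: straight-line transects and low-elevation point
  clusters; these drive the observer-bias field.

Species (`simulate_species`) have log-linear intensity in the six
standardized predictors. The GDD coefficient alternates sign across
species (uniform |β| in [0.6, 1.4]): half cold-adapted, half
thermophilic; other coefficients are N(0, 0.45²). Intensities are
normalized so the *expected sampled count after bias thinning* equals
`expected_points` (default 2000, matching the order of a well-recorded
species after capping). Sampling thins a Poisson draw by a detection
field log-linear in sqrt distance-to-road, sqrt distance-to-city and a
favoured-country indicator — the same functional family as the bias
covariates offered to the models, so the correction machinery is
genuinely exercised. A pure-birth phylogeny (dendropy) and four traits
evolved by Brownian motion on it give correlated-but-distinct
phylogenetic and functional structure. Dispersal abilities are
log-uniform in d_max over [10, 3000] m/yr (spanning > 2 orders of
magnitude) with d_min = d_max/10 and a 2-year maturity age. Expert
elevational test ranges are the 5th–95th percentile of each species'
*noiseless* intensity over the elevation gradient — derived from truth,
never from samples, mirroring the independence of an expert floristic
test set.

What the generator does **not** emulate: spatial aggregation of records
within popular sites beyond the smooth bias field, taxonomic misID noise,
temporal trends in recording, non-equilibrium occupancy, biotic
interactions, and realistic climate physics. Passing tests therefore
show the *machinery* is correct under the stated statistical assumptions,
not that real-data results would be recovered.

## Point-process models

The intensity of species records per unit area is
λ(x) = exp(β₀ + βᵀz(x) + γᵀb(x)) with z the standardized climate/soil
predictors plus one-hot land-cover dummies (reference = most frequent
class) and b the three bias covariates. The likelihood integral is
approximated by Berman–Turner quadrature: uniform random background
points, each carrying weight (total area)/(n quadrature points);
presence points carry an ε share (1e-9 of the area each) so weights sum
exactly to the study area. The weighted Poisson regression is fitted via
statsmodels GLM; the elastic-net penalty (mixing α, default 0.5, never
on the intercept) uses `fit_regularized`, with the penalty strength
chosen from a small grid (1e-2, 1e-3, 1e-4) by 5-fold cross-validated
predictive deviance on spatial blocks. Quadrature size is chosen by
doubling from n0 = 1000 until the unpenalized log-likelihood changes by
< 1%, with at most 8 doublings (warn and keep the largest scheme
otherwise).

Numerical notes: constant design columns (absent land-cover classes) are
dropped before fitting; a fit with all presences in one cell is refused;
non-finite coefficients raise rather than propagate. Cross-validation
fits use a reduced iteration budget (the ranking of penalty strengths is
insensitive to late-stage refinement); the final fit uses the full
budget. The penalty strength is selected once per (species, land-cover
variant); evaluation folds refit the coefficients at that strength
rather than re-searching the grid per fold — a nested search would
multiply the fit count several-fold without changing what the evaluation
measures at this scale.

**Evaluation** partitions the grid into 10 contiguous rectangles (2×5
tiling) paired into 5 folds by opposite corners. Each fold's model is
fitted on the other folds and scored on the left-out fold with bias
covariates at 0, against presence/absence labels derived from the
species' elevational test range. TSS is scored at the fold's maxTSS
threshold on the 99th-percentile-rescaled intensity; the continuous
Boyce index uses overlapping windows (width = range/10, 100 steps) and
Spearman rank correlation of the predicted-to-expected ratio against
window midpoints. A model is discarded only when *both* mean TSS and
mean Boyce fall below 0.3; a missing (undefined) Boyce counts as
below-cutoff for this rule.

**Thresholding** is the one genuinely under-determined step: intensities
have no natural (0,1) scale. We divide by the 99th percentile of the
species' current ensemble map (clamped at 1) — robust to single-cell
outliers — and threshold at the mean of the retained models' maxTSS
thresholds computed on the full current map. Both the rescaling quantile
and the thresholding behaviour are configurable.

## Dispersal automaton

Initial occupancy is the current binary range with standing populations
mature. Yearly update order: (1) extirpate occupied cells unsuitable
under the target-period habitat — the future binary applies from year 1
(no interpolated habitat series; the conservative reading), (2) every
mature cell attempts colonization of each empty suitable cell within
d_max, with per-source success probability 1 for d ≤ d_min, exponential
decay from 1 to 0.01 at d_max, 0 beyond; at most one colonization per
target per year (one uniform draw per target per year, so widening the
kernel is monotone under a fixed seed), (3) ages increment; colonized
cells become sources after `ini_mat_age` years (default 2). Simulation
horizon is horizon − 2000 years (50 for 2050, 80 for 2080), anchoring
the current period at ~2000. The combined per-target probability is
computed as 1 − exp(Σ log(1−p)) via FFT convolution of the mature-cell
mask with the log-miss kernel.

Extirpate-before-colonize is a deliberate order choice; the alternative
(colonize first from doomed cells) would let one extra propagule
generation escape and is not obviously more faithful.

## Diversity, endemism, rarity

All tree metrics operate on a branch table (length + tips-below
membership), built from the Newick phylogeny or from the functional
dendrogram (Gower distance on the four traits — for continuous traits,
range-normalized Manhattan — clustered by UPGMA, hence ultrametric).

- TD = exp(Shannon) of within-cell intensity shares; PD/FD at q = 1 are
  reported as *effective branch length* T̄·exp(−Σ (L_b a_b/T̄) ln a_b)
  (a star tree with unit branches collapses this to TD exactly).
- Relative metrics (rPD, rFD, rPE, rFE) are OLS residuals of the metric
  on TD (or WE) with a quadratic term, over occupied cells. The
  regression direction is metric ~ TD: "how much tree diversity given
  the species count".
- Endemism: WE_i = Σ_s a_is/A_s; PE/FE replace species by branches, a
  branch's per-cell intensity being the **max** over descendant tips
  (union-of-ranges semantics; `sum` available as a switch). Cell sums
  conserve S and total branch length by construction.
- Rarity: distinctiveness D_s = mean pairwise patristic distance
  rescaled by the max pairwise distance; restrictedness
  R_s = 1 − occupancy share; cell score = intensity-weighted mean of
  D_s·R_s over present species. Prioritization weights are the sum of
  the phylogenetic and functional D·R facets, each normalized to mean 1
  so neither scale dominates.

## Prioritization

Greedy removal with exact one-at-a-time updates (no batch removal — the
coarse grid is small enough that exactness is affordable), ties broken
toward the lowest cell index. CAZ removes argmin over cells of
max_j w_j a_ij / remaining_j; ABF of Σ_j w_j [R_j^z − (R_j − a_ij/A_j)^z]
with z = 0.25 by default (the conventional concavity of the external
software; configurable, and z = 1 telescopes to a static weighted sum).
Expansion mode removes all free cells before any PA cell, so the PA
network is ranked strictly above the free landscape and the top
fraction of *free* cells is the proposed expansion. Cost is uniform.
Cross-scenario "expanded PAs" are cells in the top-20% expansion of ≥ 2
of the current/2050/2080 rankings; with highly concordant scenario
priorities the resulting protected share can reach, but not exceed, the
PA share plus the full top fraction of free land.

## Reported summaries

Per-species percent range change is |future−current|/current × 100,
signed by direction, on coarse occupied-cell counts; |change| < 1%
counts as "stable". Elevational classes use fixed belt thresholds
(colline < 700 m, montane < 1500, subalpine < 2200, alpine < 3000,
nival above) on the multiplicity-weighted 95th percentile of elevation
at record locations (type-7 interpolation). The directional sanity
check computes the intensity-weighted mean elevation of suitable
habitat, current vs the warmest horizon, per species, and reports the
fraction of cold-adapted species (true GDD coefficient < 0) shifting
upslope.

## Problem sizes and determinism

Default study conditions: 120×120 fine cells, 25 species, ~2000 expected
records per species, 2 horizons × 1 SSP × 2 GCM replicates, two
land-cover model variants. The full pipeline and the acceptance script
each run in minutes on one CPU. Every stage is a pure function of
(parameters, seed); stage outputs are cached under the run directory
keyed by a hash of parameters plus upstream hashes, so unchanged reruns
are pure cache hits and a parameter change reruns only the affected
tail.

## Known limitations

- The environmental-bias-correction target distribution (cluster areal
  share) and its chi-squared detection rule are our design; uniform
  targets are available as a switch.
- Boyce windows and the spatial-block tiling geometry are fixed
  conventions, not fitted.
- No per-year habitat interpolation in the automaton; no long-distance
  dispersal, barriers, demography or competition.
- The synthetic world's scenario spread (GCM noise amplitude) is a free
  parameter with no empirical anchor.
- q ≠ 1 Hill profiles, beta-diversity/turnover and trait imputation are
  out of scope.
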