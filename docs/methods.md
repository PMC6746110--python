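# Methods

This note records the models the package implements, the numerical
choices behind them, and what the synthetic data does and does not
emulate.

## Diversity metrics

All three indices are per-community (per grid cell) functions of a
presence/absence row over the species pool.

**TD** is the row sum.  **PD** is Faith's phylogenetic diversity: the sum
of branch lengths of the subtree spanned by the community's species,
averaged arithmetically over the tree ensemble.  **FD** applies the same
branch-sum operator to the functional dendrogram, unrescaled.

Two spanning conventions exist because the literature is split on
single-species communities.  The default, *root-inclusive*, sums every
edge on the union of tip-to-root paths: singletons score their root-path
length, the metric is monotone under species addition, and every mapped
cell (including richness-1 cells) is well defined.  The alternative,
*mrca*, restricts the sum to edges below the set's most recent common
ancestor, so singletons score 0.  Both are available (`pd_convention`);
everything downstream is convention-consistent.  Empty cells report 0
rather than erroring so whole-grid tables are total.

The branch sum is computed by climbing tip-to-root paths with an early
stop at already-visited nodes, O(richness × depth) per community; a
brute-force "mark every edge whose subtree intersects the set" oracle
backs it in the tests over all subsets of small trees.

## Functional dendrogram

Gower similarity over the 14-column trait table: continuous and
percentage traits contribute `1 − |xᵢ − xⱼ|/range` with ranges taken over
the **full species pool** (one global dendrogram, not per-community
rescaling); binary traits contribute exact agreement; each of the 14
columns has weight 1 (percentage-composition columns are *not*
down-weighted by group — recorded as a deliberate literal reading, and
the weights are the obvious place to change it).  Missing values are
pairwise-deleted, never imputed; zero-range traits are dropped with a
warning; a species pair sharing no observed trait is an error.
Right-skewed continuous traits are used untransformed by default; a
config switch applies log10.

UPGMA is implemented in the package rather than taken from scipy because
the merge tie-break must be platform-independent and order-independent:
ties on the minimum average dissimilarity go to the pair whose
lexicographically smallest member label is smallest.  scipy's average
linkage serves as an independent cross-check on tie-free matrices in the
tests.  Node heights are **half** the merge dissimilarity, so the
cophenetic tip-to-tip distance equals the dissimilarity at which two
groups merged; FD values are therefore on the same scale as published
dendrogram-FD conventions that use cophenetic = merge height.

## Null models

The null hypothesis fixes each community's richness and randomizes
phylogenetic/functional structure by permuting species labels across tips
(999 replicates by default).  One shuffle per replicate is shared by all
cells.  Because a fixed community under a tip shuffle is exactly a
uniform random same-size tip set, the metric is evaluated once per
(richness level, replicate) and shared across cells of equal richness;
the literal per-cell path is retained and the two are asserted equal on
fixtures where equal-richness cells share a composition.

SES uses the sample SD (n−1).  The quantile score is
`1 + #{null < obs} + ⌊#{null = obs}/2⌋` — the half-tie rule is our fixed
choice; ties only arise on degenerate fixtures.  Cells whose null SD is
zero up to float rounding (empty cells, full-pool cells) are flagged
degenerate and reported not-significant.  Classification thresholds are
≤ 25 / ≥ 975 of 999 (configurable; the scaled-down demo uses 5/195 of
199, the same two-sided 5%).

Observed PD is the ensemble mean.  For the null, two readings exist: a
single-tree null (first ensemble tree; default) and a full-ensemble null
(`ensemble_null=True`) in which each replicate applies one permutation to
every tree and averages.  With real posterior tree sets, which share taxa
and calibration, the two differ negligibly.  With *independently
simulated* trees the single-tree null is biased for an ensemble-mean
observation — the first tree's branch-length total is an arbitrary draw —
so calibration checks on synthetic data use the full-ensemble null, and
the generator rescales every simulated tree to unit root-to-tip depth
(dated trees share the present).  Calibration on neutral assemblies
(300 cells, 60-species pool, R = 999) yields ~5% two-sided significance,
mean SES ≈ 0 and SD(SES) ≈ 1.

## Regionalization

Named range-restricted species are dropped first (the species are config,
not hard-coded), then cells below the richness floor (default 4) — the
order matters and is fixed.  Sørensen dissimilarity is computed on the
filtered matrix, and the cells are clustered with the same UPGMA engine.
The group count k is a user decision (default 12 at full scale, 4 in the
demo): no elbow detection is attempted, but the within-group mean
dissimilarity curve over k = 1..15 (pairs pooled across groups; the k = 1
point is the grand mean of the matrix) is always emitted as the evidence
a user would assess.  An O(n²) memory guard warns above 5,000 cells.

Hemisphere assignment for the driver models: the study derives the
north/south split from its faunal clusters, which works because real
species ranges are spatially cohesive.  The synthetic generator
deliberately has no range geometry, so its Sørensen clusters carry no
geographic signal and cluster-mean-latitude labels would misassign cells;
the pipeline therefore defaults to the explicit cell-latitude rule
(`hemisphere_rule="latitude"`), with the cluster-derived split available
for real data.  Per-cluster assignment uses an explicit mapping when
given, else the sign of the cluster's mean latitude (exactly zero demands
a mapping).

## Environmental drivers

*Productivity summaries* over a (pixels × pixels × years × dekads) stack:
peak = per-pixel 95th percentile over all values, averaged over pixels;
seasonality = per-pixel mean over years of the within-year SD; interannual
variation = per-pixel SD of the yearly 95th percentiles; heterogeneity =
mean SD of full 3×3 windows of the pixel-mean map (undefined below 3×3).
All SDs use n−1 and are computed on slices centered on their first
element, which is mathematically identical (SD is translation-invariant)
but returns exactly 0 on constant input.  The same operators serve the
AET-like stack.

*VIF screening* is iterative — drop the single worst predictor, recompute,
repeat while max VIF exceeds the threshold (10) — rather than single-pass,
which can over-drop; the full drop trace is returned so either reading is
auditable.  Exact collinearity reports VIF = ∞ and goes first; exact ties
drop the later column.

*Moran's I* uses row-standardized lattice-contiguity weights with a
permutation p-value folded two-sidedly around E[I] = −1/(n−1).  Rook
(4-neighbor) contiguity is the default: queen contiguity's diagonal
neighbors share the sign of an alternating pattern and largely cancel it,
so rook is the sharper detector of small-scale structure; queen is
available via `contiguity=`.

*Random forests*: 1,000 trees, `min(11, p)` candidate predictors per
split, bootstrap resampling, node-size-weighted MSE splitting (the
standard variance-reduction criterion — taken as the meaning of "weighted
mean-squared error" splitting).  OOB variance explained is
`100·(1 − MSE_OOB/Var(y))`.  Importance is the OOB permutation increase
in MSE, averaged over trees; per-tree OOB membership is reconstructed
from the estimator's seeded bootstrap draw and verified against the
forest's own OOB predictions in the tests.  Negative importances are
clipped to 0 and the vector scaled to sum 100; latitude and longitude
stay in the model (they absorb spatial autocorrelation) but are excluded
from the importance report by default, with scaling over the reported
set.  Minimal depth is the mean depth of a predictor's first split,
charging absent predictors the tree's height.  Partial dependence fixes
the predictor at 25 evenly spaced values of its observed range; the SE
band is the SD of per-tree partial values over √T.

## Synthetic data

The generator emulates the *shape* and the *processes* of the study
inputs, not their geography:

* trees: birth-death simulations conditioned on the extant tip count,
  rescaled to unit depth; labels are attached in each tree's own leaf
  order so the species-to-topology association varies across the
  ensemble, as across posterior samples;
* traits: Brownian motion along the first tree (continuous), thresholded
  liabilities (binary), softmax-normalized liability vectors × 100
  (percentage groups — compositions sum to 100 by construction);
* environment: seasonality rising steeply with |latitude| in the northern
  half and weakly in the south, unimodal peak productivity, a dekadal
  NDVI stack whose summary statistics recover those target fields
  (cosine annual cycle with amplitude `season·√2`, per-pixel baseline
  jitter, per-year offsets), correlated bioclim-style fields, an exact
  duplicate and a near-linear combination planted for the VIF screen,
  and unstructured hydrogeomorphology columns;
* assembly: *neutral* (uniform subsets of drawn richness), *filtering*
  (Gaussian kernel between a designated niche trait and the linked
  predictor, both z-scored, so σ is in trait-SD units; at underflow the
  σ→0 limit selects the nearest trait values deterministically), and
  *limiting similarity* (sequential admission rejecting candidates within
  Gower distance δ of a resident; early pool exhaustion fills the cell to
  the feasible maximum and flags it).

Demo conditions (one choice, made once): 60 species, 10 trees, a 20×15
grid spanning 55°S–70°N, Poisson richness with mean rising from 4 at the
equator to 16 at 70°N and 9 at 55°S, σ = 0.4, δ = 0.22, 199 null
replicates with cutoffs 5/195, 4 region groups, 300-tree forests.  These
sizes keep a full pipeline run near ten seconds while leaving every
qualitative contrast detectable.

What passing tests on this generator do **not** show: robustness to
spatially cohesive ranges (none are simulated), to trait data whose
missingness is informative, to non-ultrametric or wildly varying
chronograms, or to the sampling artifacts of real range maps.  The
generator is a controlled instrument for verifying that each estimator
recovers what was planted, not a model of real biogeography.

## Known limitations

* UPGMA is O(n³) time / O(n²) memory; at the real study's ~12,500 cells
  the Sørensen matrix alone is ~1.2 GB and clustering is slow — the
  implementation targets analysis-scale grids and warns accordingly.
* The filtering kernel links one trait to one predictor; multi-trait
  niches are out of scope.
* "Distance to water weighted by elevation" has no published formula and
  is accepted only as an input column.
* GIS ingestion (polygons, projections, rasters) is out of scope; the
  community matrix is an input.
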