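# Methods

## The model

`netrep` quantifies how well a network of environmental observation sites
represents a gridded landscape, and which site best represents each
location, using nothing but multivariate environmental similarity — no
clustering, no classification, no spatial smoothing.

**Feature space.** The input is a stack of co-registered continuous
raster layers (climatic, edaphic, topographic drivers). Over the jointly
valid cells the layers are standardized — centred and, by default, scaled
to unit variance, because the layers carry incommensurable units and an
unscaled decomposition would be dominated by the largest-magnitude layers
— and decomposed by SVD (scikit-learn's PCA). The leading components
whose cumulative explained variance reaches a threshold (default 0.90)
define the score space; every distance below is Euclidean distance in
that space. The fit can optionally be restricted to a masked subset of
cells (e.g. working lands only); the default fits on all valid cells.
Component signs are fixed deterministically (largest-magnitude loading
positive) so results are reproducible across linear-algebra backends.

**Representativeness.** For a site-network centroid with score vector
*v* and a grid cell with score vector *u*,

  r(v, u) = 1 − ‖v − u‖ / D,

clipped to [0, 1]. The divisor *D* makes the distance term a normalized
distance; two methods are provided:

* `bbox_diameter` (default): the Euclidean norm of the per-component
  (max − min) range vector over all valid cells. It depends only on the
  landscape, never on the site set, which buys three properties at once:
  r is guaranteed to lie in [0, 1]; adding sites can only raise a
  network's surface (monotone network growth); and values from different
  networks on the same landscape are directly comparable.
* `observed_max`: the exact maximum (centroid, cell) distance, found in
  a separate exhaustive pass. The furthest observed pair then scores
  exactly 0, but the constant changes whenever the site set does.

Per-site layers aggregate that site's centroid layers cellwise. The
default aggregation is `max`; `mean` and `sum` are available, with `sum`
flagged because summed layers exceed 1 and stop being a normalized
index. The network layer is always the cellwise maximum over *all*
centroids, independent of the site aggregation, so a sampled centroid's
own cell always scores exactly 1 (self-representation) and the winner's
site value equals the network value under `max`.

**Constituency.** Each (optionally mask-restricted) valid cell is
assigned to the site with the highest representativeness there — a pure
argmax, ties broken to the earlier-listed site. A per-cell top-N ranking
(default 3) of runner-up sites is stored; the full sorted ranking is
available through a streaming iterator. Per-(site, class) summaries give
constituency areas (cell count × cell area, reported in hectares) and
representativeness distribution statistics. Sites are labelled
*generalist* (large constituency, high mean representativeness),
*specialist* (small constituency, equally high representativeness) or
*double-duty* (10th-percentile representativeness more than 0.2 below
the 0.8 floor — best available but a forced fit for part of its
constituency). The area split (median), floor (0.8) and gap (0.2) are
conventions of this package, configurable, not measured quantities.

**Complementarity.** Several networks sampled on the same feature space
are compared under one shared `bbox_diameter` constant (per-network
`observed_max` constants would make the comparison incoherent). The
best-network map is a per-cell argmax over the networks' network-level
surfaces, ties resolving to the home network (the conservative "no
change needed" reading); the improvement surface is the combined maximum
minus the home surface, which is non-negative by construction. Sister
centroids can be filtered to those whose containing cell carries a
working-lands class. Candidate locations for new sites are nominated at
the lowest cells of the network surface, greedily spaced by a minimum
separation (default 5 cells) so they are not all drawn from one pocket.

## The synthetic landscape generator

The generator is first-class, tested code: it produces the study
conditions every downstream stage is exercised under.

* **Fields.** Each layer is a stationary Gaussian random field built by
  spectral synthesis: white noise, Fourier low-pass with a Gaussian
  transfer function of e-folding scale `correlation_length` (default 12
  cells), standardized. Layers are then mixed through the symmetric
  square root of the target cross-correlation matrix (eigenvalues
  clipped at zero, tolerating near-PSD input) and re-standardized.
  Periodic boundary artifacts of the FFT route are accepted.
* **Default cross-correlation.** Compound symmetry with ρ = 0.92: every
  layer shares one dominant gradient plus independent local variation.
  Real driver stacks (bioclim + soil) are strongly co-varying, and a
  dominant shared gradient is precisely what makes a stratified site
  network recoverable as constituencies — with weaker sharing, the minor
  sample components (inflated at low effective spatial degrees of
  freedom) regionally override the gradient and the planted structure is
  not recoverable by *any* distance-based method. The default landscape
  is therefore deliberately gradient-dominated; specs with arbitrary
  cross-correlation matrices are fully supported.
* **Mask.** The four working-lands classes (non-working, grazingland,
  cropland, mixed, laid out in that order along the latent gradient) are
  carved from quantile thresholds of a designated layer; spatial
  coherence of the patches comes entirely from the layer's
  autocorrelation. Default class proportions 0.35 / 0.43 / 0.20 / 0.02
  mirror the approximate conterminous-US land-area fractions of those
  classes.
* **Networks.** `random` placement draws anchor cells uniformly;
  `stratified` splits a designated gradient layer (default: the
  cross-layer mean, i.e. the shared gradient) into `n_sites` quantile
  strata, anchors each site at the cell whose gradient value is nearest
  its stratum median, and keeps jittered centroids (rounded Gaussian
  offsets, default σ = 2 cells, bounded retries) inside their own
  stratum — a stratified site samples its stratum, not its neighbour's.
* **Seeding.** All generators are pure functions of (spec, seed). The
  landscape seed expands via `SeedSequence` into one child stream per
  layer, in layer order; networks carry their own seed.

**What the generator does not emulate:** real geography (no coastlines,
no elevation structure), anisotropy, non-Gaussian marginals, temporal
structure, and the block-structured correlation of real driver sets
(climate block vs soil block). Passing tests therefore demonstrate the
*method's* correctness and invariances, not calibration of any real
network's representativeness values.

## Numerical choices

* All distance accumulation is double precision regardless of storage
  precision; tiles over cells change nothing but peak memory (verified
  to ≤ 1e-12 across tile sizes).
* Clipping of r to [0, 1] happens at the centroid level (so `mean`/`sum`
  aggregate clipped maps); under `bbox_diameter` it can trigger only at
  floating-point edges, and clip counts are logged.
* Co-registration of transforms uses a 1e-9 relative tolerance.
* Dominant-type resampling drops trailing partial blocks with a logged
  warning; count ties break to the lowest code; invalid fine cells do
  not vote, and a coarse cell is invalid only if its whole block is.
* Half-open cell membership: a point on a shared edge belongs to the
  cell whose west/north edge it lies on (floor of fractional indices).
* Polygon centroids are area-weighted geometric centroids and may fall
  outside their polygon; no interior-point guarantee is made.
* Centroids on invalid cells are dropped with a logged count; centroids
  outside the grid extent are a hard error (mis-registration).
* A landscape whose valid cells are identical in score space has an
  undefined representativeness (zero diameter) and is rejected.
* KDE summaries use Silverman's bandwidth, evaluated on a grid extended
  slightly beyond [0, 1] so each class density integrates to ≈ 1;
  constant-valued classes get statistics but no curve.

## Design choices where the design was open

* **Site aggregation `max` rather than `sum`.** Summed per-site layers
  are not bounded by 1, cannot equal the network maximum at the winning
  cell, and make the constituency argmax depend on centroid counts
  rather than environmental match. `max` keeps per-site, network and
  constituency layers mutually consistent; `sum` and `mean` remain
  available for sensitivity work, with `sum` explicitly flagged.
* **The normalization divisor** is not uniquely determined by the
  requirement that distances be "normalized between 0 and 1";
  `bbox_diameter` was chosen as the default for the monotonicity and
  comparability arguments above, with `observed_max` kept for fidelity
  experiments.
* **Joint validity.** When any layer is nodata at a cell, the cell is
  excluded everywhere (the strictest mask).
* **Mask behaviour.** Representativeness can be computed unmasked;
  constituency refuses to run without a mask rather than silently
  assigning non-working cells.

## Problem sizes

The default test-suite and demo sizes are 128×128 grids with 15 layers
and up to ~500 centroids (the full pipeline completes in seconds);
oracle-equivalence checks run on ≤ 12×12 grids where exhaustive
double-loop references are exact. The engine itself is tiled and has no
structural limit: cost scales as (cells × centroids) distances per pass.

## Known limitations

* No reprojection: all inputs must already share one grid.
* The representativeness index is a linear transform of Euclidean
  distance; it inherits PCA's linearity and says nothing about factors
  outside the layer stack (management, socio-economics, biotic context).
* `observed_max` normalization makes values incomparable across site
  sets; cross-network comparisons must use the landscape-derived
  constant.
* The generalist/specialist/double-duty labels are threshold
  conventions, intended for triage rather than inference.
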