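# Methods

This note documents the models implemented in `scmtop`, the parameter
choices that matter, the conventions adopted where the underlying method
leaves details open, and what the synthetic validation data does and does
not establish.

## Input model and coordinate conventions

The package consumes per-nucleus segmentation records (JSON map of nucleus
id → bbox, centroid, contour, integer type code) in the dialect produced by
HoVer-Net-style networks.  Type codes follow the PanNuke five-class
convention: 1 neoplastic → tumor, 2 inflammatory, 3 connective → stroma,
4 dead, 5 non-neoplastic epithelial → normal; code 0 (unlabelled) is
dropped with a logged count.  Coordinates are 0-based pixels, x rightward,
y downward; every distance is Euclidean in pixels.  The default resolution
is 0.25 μm/px, so the 100-px graph threshold corresponds to 25 μm and a
200-μm spot to 800 px.  Dead (necrotic) nuclei are removed before any
profiling; normal cells are kept in composition summaries but excluded
from graphs and feature extraction, which cover tumor, inflammatory and
stroma cells only.  Nuclei touching slide borders are kept.

## Per-nucleus features

**Morphology (14 features).**  The contour polygon is rasterized to a
binary mask.  Area is the mask pixel count; AreaBbox the bounding-box
area; Extent = Area/AreaBbox; Solidity = Area / convex-hull area;
Major/MinorAxisLength and CellEccentricities come from the ellipse with
equal central second moments; Elongation = 1 − Minor/Major; Perimeter uses
the Crofton estimator (markedly less rasterization bias than chain-code
length, important for Circularity = 4π·Area/Perimeter², which should
approach 1 for a disk); the four curvature statistics
(CurvMean/Max/Min/Std) are computed on the contour resampled to 128 points
of uniform arc length and Gaussian-smoothed with σ = 2 samples, using
κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} with periodic finite differences.
Without smoothing, rasterization noise dominates the curvature extrema.
Degenerate (collinear, zero-area) contours raise an error naming the
nucleus.

**Texture (9 features).**  The grayscale bbox patch is quantized from
8-bit to 32 gray levels.  The co-occurrence matrix uses four 1-px offsets
(0°, 45°, 90°, 135°), is symmetrized and normalized per offset, and —
unlike stock GLCM implementations — counts only pixel pairs whose both
endpoints lie inside the nuclear mask, so background never contaminates
the statistics; this mask-restricted tabulation is implemented directly
(a small numpy kernel) because no installed library supports it.  ASM,
Contrast, Correlation, Entropy (natural log) and Homogeneity are averaged
over the four offsets; Correlation of a zero-variance patch is defined as
0, and a mask too small for any pixel pair falls back to the single-level
conventions (ASM = Homogeneity = 1, Contrast = Entropy = 0).  Intensity
statistics (mean, population SD, max, min) use masked pixels only.
Texture is optional: with no image supplied the columns are absent and
downstream stages use morphology alone.

## Multilevel pairwise graphs

For each ordered type pair, candidate directed edges connect every cell of
one type to its k = 5 nearest cells of the partner type (within-type kNN
when the types coincide); candidates are filtered at distance < 100 px
(strict, so an edge of exactly the threshold length is deleted) and
undirected-deduplicated.  Restricting the neighbor search to the partner
type is essential: searching among all cells would leave heterotypic
graphs nearly empty inside homogeneous regions.  kNN ties break by nucleus
id for determinism.

Per-cell topology per graph: Nsubgraph (connected-component size
including the cell), Min/MeanEdgeLength over incident edges (both set to
the 100-px upper limit for isolated cells), Degrees, Coreness (k-core
number in the whole graph), Eccentricity and shortest-path centralities
computed within the cell's component — Closeness = (n_c−1)/Σd (0 when
isolated), HarmonicCentrality = mean of 1/d, Betweenness with
Betweenness_normed = B/((n_c−1)(n_c−2)/2) (0 when n_c < 3),
Eccentricity_normed = eccentricity / component diameter (0 for
singletons).  ClusteringCoefficient is the local transitivity, defined as
0 for degree < 2; it is emitted for homotypic graphs only, since in
bipartite-by-construction heterotypic graphs it is structurally zero or
undefined.  Each cell's three per-graph feature blocks are concatenated
with graph-label prefixes (e.g. `T-I_Degrees`).

**StromaBlocker** quantifies the stromal barrier between an inflammatory
cell and nearby tumor cells: for each inflammatory cell, take its k = 5
nearest tumor cells within R = 300 px and count stroma centroids within a
corridor of half-width w = 15 px around each straight segment; the feature
is the mean count (0 with no tumor cell in range).  This corridor-count
construction is a reconstruction from the feature's stated purpose — the
exact original formula is not public — and all three parameters are
configurable.

## Cell clustering and extrapolation

Per-type clustering follows the standard single-cell recipe: sample 0.5%
of cells per slide (at least one per nonempty slide), pool, log1p,
scale each feature to unit variance (zero-variance features dropped with a
warning), project to ≤ 50 principal components, build an undirected
15-nearest-neighbor graph in PCA space and partition it with Leiden
(RBConfiguration quality, resolution 1.0 by default, fixed seed).  The
edge-length sentinel 100 is used as-is in the feature matrix — it is part
of the feature semantics, not missing data.

Cluster counts from Leiden are resolution-dependent and are not treated as
a validated quantity; the planted-recovery tests therefore run at a coarse
resolution (0.1), where well-separated feature blobs — which are
disconnected components of the kNN graph — are recovered exactly.  At
resolution 1.0 modularity optimization subdivides even a single isolated
blob, a well-known property of the quality function, not an implementation
artifact.

**Extrapolation** extends a fitted model to a new cohort with the
reference memberships held fixed: the new cohort is preprocessed with its
own log/scale statistics (using the reference scaling is available by
config), the joint PCA space is recomputed on the concatenated matrix, and
Leiden runs on the joint kNN graph with reference labels frozen
(`is_membership_fixed`) and new cells starting from random initial
clusters.  A new cell that ends in a community containing no reference
cell is reassigned to the nearest reference-cluster centroid in the joint
reduced space, so extrapolation never invents a label.  The validation-
cohort sampling default is 10%.

The aggregated inflammatory cell (AIC) score of a sample is the sum of
the within-type fractional abundances of the locally aggregated
inflammatory clusters (INF0, INF1, INF6, INF7 by default; configurable).

## MITH

Features (the 14 morphological, plus the 9 texture features when
available) are z-scored across all tumor nuclei of all samples; robust
median/MAD scaling is available by config.  A sample's MITH is the mean
over features of the **population** (divide-by-M) standard deviation of
the normalized feature across the sample's tumor nuclei.  The population
convention makes MITH invariant under duplicating a sample's nuclei;
samples with fewer than two tumor nuclei are flagged missing.  MITH is
computed on all tumor nuclei, not the clustering subsample.

## Spots, spatial correlation, modules

Each slide is tessellated into non-overlapping 200-μm squares ("spots") on
a grid anchored at pixel (0, 0); a cell at (x, y) belongs to spot
(⌊y/s⌋, ⌊x/s⌋) with half-open intervals, so boundary cells go to the
higher-index spot.  Partial border spots are kept.  Spot fields include
the empty spots of the occupied bounding grid, so absence of cells is
informative for the spatial statistics.

Spatial weights are binary rook adjacency — up to four orthogonal grid
neighbors — used identically for the bivariate correlation and Moran's I
(k-nearest spot centers available as an alternative).  The bivariate
statistic C(x, y) reduces exactly to Moran's I when x = y, an identity the
tests verify numerically; fields with zero variance return 0 with a
degeneracy flag.

Per-sample cluster × cluster correlation matrices are averaged element-
wise across samples ignoring degenerate-flagged entries (a pair degenerate
in every sample is an error), symmetrized as (C + Cᵀ)/2, and Ward-
clustered on the matrix rows; the tree is cut into a configured number of
modules (default 8).  Module names are ordinal (Module1…ModuleN by first
cluster appearance).  Per-spot module scores are the fraction of the
spot's cells whose cluster belongs to the module (scores sum to 1 on
nonempty spots); spots are assigned by argmax with ties toward the lower
module index, and zero-cell spots are labelled Module0_NC.  Module-score
fields are characterized by Moran's I per sample.  Intra-/inter-module
variation of per-spot cell-type proportions uses population SDs;
Module0_NC spots are excluded, and single-spot modules contribute SD 0
with a warning.

## Ecotypes

A sample's composition is the fraction of its classified spots per module;
Module0_NC is excluded from the denominator by default (configurable).
Ward clustering of the composition vectors defines ecotypes; the cluster
number is selected over 2–10 by maximizing the Silhouette coefficient with
the Calinski–Harabasz index as tie-break (the two indices are combined
this way because no canonical combination rule exists; Silhouette is
bounded and scale-free, hence primary).  The classifier is an RBF-kernel
SVM (kernel configurable) trained on a stratified 80/20 split and
evaluated by held-out weighted F1.  Compositions are scale-free, so
ecotype labels are invariant to uniform scaling of a sample's spot counts.

## Synthetic data

The generator emulates exactly the structures the pipeline measures:

- **Fields**: per-type homogeneous Poisson, Thomas cluster (Poisson
  parents, Gaussian offspring) or region-restricted processes with
  intensities in cells/mm²; nuclear contours as ellipses with radial
  Fourier perturbation (modes 2–5, 24 vertices); per-nucleus 8-bit patches
  with Gaussian gray levels and optional stripe texture.  The perturbation
  amplitude *dispersion* across nuclei plants a MITH ground truth: more
  dispersion ⇒ more shape heterogeneity ⇒ higher MITH (tested monotone).
  Thomas-clustered fields yield higher I-I degrees and shorter minimum
  edge lengths than Poisson fields of equal intensity (tested).
- **Cohorts**: each slide is tiled into 500-μm regions; every region draws
  a region kind from its sample's archetype prior and co-places that
  kind's cell clusters as Gaussian blobs (σ = 80 μm, ~30 cells per cluster
  per region).  Defaults: 40 samples, 2000-μm slides, four region kinds of
  two clusters each, four archetypes with 0.7 prior mass on their own
  kind.  Module discovery should recover the cluster → kind partition and
  ecotype clustering the archetype labels; both recoveries, plus the SVM's
  held-out F1, are exercised end to end in the tests and the acceptance
  script.  In this cohort all planted inflammatory clusters belong to the
  aggregated set, so the expected mean AIC score is 1.

Everything is driven by `numpy.random.default_rng` seeds; identical seeds
give bit-identical output.

What the synthetic data does **not** emulate: stain variation and imaging
artifacts, segmentation errors and misclassified types, realistic nuclear
chromatin texture, cell-density gradients within regions, or the
correlation structure of real morphology features.  Passing tests
therefore establish the correctness of the computations and the
recoverability of planted structure, not clinical performance on real
WSIs, whose headline statistics depend on large controlled-access cohorts.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by design: random
graph fields up to 500 cells (20 fields against an exhaustive O(n²)
oracle), 400-μm fields (~700 tumor cells/mm²) for morphology/MITH, and the
40-sample cohort (~38k cells) for module/ecotype recovery.  Tolerances:
exact-arithmetic identities (Moran's reductions, MITH oracle) at 1e-10;
rasterization-dependent morphology at 2–5%.  Isolated-cell sentinels,
degenerate contours, zero-variance features and fields, empty spots and
single-spot modules all have defined, tested behavior described above.

## Known limitations

- The StromaBlocker corridor construction is a documented reconstruction.
- Leiden cluster counts at the default resolution are not expected to
  match any particular taxonomy size; resolution must be tuned per cohort.
- Extrapolation recomputes the joint PCA space; with a very large
  reference and a tiny new cohort the space is dominated by the reference,
  which is the intended behavior but makes per-call cost proportional to
  the reference size.
- The spot grid is anchored at pixel (0, 0); no offset search is
  performed, so module scores near region boundaries depend on grid phase.
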