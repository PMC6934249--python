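# Methods

This package implements a two-stage procedure for measuring urbanization
from census data alone: (1) dasymetric disaggregation of census-unit
population counts to a fine grid with a random-forest density model, and
(2) delineation of metropolitan agglomerations from that grid by density
thresholding, contiguity, a boundary-proximity graph and modularity-based
community detection. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Gridded population intensity estimation

**Model.** For census zones z with population N_z and area A_z (ha), a
random forest regresses the natural-log population density

    y_z = ln(N_z / A_z)

on zonal means of the covariate rasters. The fitted forest is evaluated at
every grid cell's covariate values, and w_i = exp(ŷ_i) becomes a relative
weight. Counts are then redistributed within each zone:

    persons_i = N_z · w_i / Σ_{j∈z} w_j ,

so each zone's cells sum exactly to its census count — the defining
pycnophylactic property of dasymetric mapping. The modelled quantity is a
*relative* density surface; the absolute level inside each zone is pinned
by the census count, not by the forest.

**Assumptions.** The covariate–density association estimated at the zone
level is taken to transfer to the cell level (a change-of-support
assumption; it is the standard one for top-down gridded population
products). Habitability is binary: masked cells receive zero weight, with
no notion of partial habitability. Because tree ensembles cannot
extrapolate, predicted log densities are confined to the range of zone-level
training responses; the weight surface is therefore smoother and less
extreme than true cell-level density, which matters mainly when census
units are much coarser than the settlement scale.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| trees | 500 | — | large enough that OOB estimates stabilise |
| features per split | ⌈p/3⌉ | — | regression-forest default |
| cell size | 100 | m | 1 cell = 1 ha, so cell density = cell persons |
| zero-count pseudo-count ε | 0.5 | persons | keeps ln(N/A) finite without dropping zones |
| mask | binary | — | 1 = habitable |

Out-of-bag diagnostics: each zone is predicted by the trees that did not
sample it (≈37% of trees in expectation), giving `oob_mse` and
`oob_pseudo_r2 = 1 − oob_mse / Var(y)`. A constant response triggers a
warning and a model that predicts the constant (pseudo-R² reported as 0).

**Degenerate cases.** A zone whose weights sum to zero receives a uniform
allocation over its habitable cells (over all its cells if none are
habitable), so counts are conserved unconditionally. Zones with no grid
cells are an error, as are missing covariate layers (named in the message).

## Zonal geometry conventions

All geometry lives in one projected metric CRS; grids are north-up with
square cells. Cell membership everywhere uses the cell-centre rule: a cell
belongs to a polygon iff its centre is inside (or on the boundary of) it.
A centre lying exactly on a shared zone boundary goes to the zone with the
lexicographically smallest id — a deterministic tie-break that makes zonal
statistics and redistribution agree exactly. Raster distances
(`signed_distance_to_class_edge`) are centre-to-centre Euclidean, negative
inside the target class; nearest-neighbour resampling assigns each output
cell the value of the source cell containing its centre.

## Delineation

1. **Threshold.** Cells with density ≥ τ are selected; τ defaults to 7.5
   persons/ha, with 5 and 10 as the standard sensitivity settings. The
   comparison is inclusive (a `strict` flag flips it); nodata is never
   selected.
2. **Region grouping.** Connected components of selected cells under rook
   (4-)contiguity by default, dissolved into polygons. The 150 m graph
   stage, not diagonal adjacency, supplies the "one cell skipped over"
   reach, so queen contiguity is available but not the default.
3. **Hole filling.** Each polygon is replaced by its exterior ring, so
   enclosed parks, hills and water count as part of the urban area. Filling
   is idempotent and never shrinks a polygon.
4. **Minimum area.** Polygons below 2 ha (about two cells) are removed —
   after hole filling — to suppress single-cell noise in the estimated
   surface.
5. **Population integration.** A settlement's population is the sum of
   persons at cells whose centres fall inside its filled geometry,
   including formerly below-threshold hole cells.
6. **Proximity graph.** Vertices are settlements; an edge joins two
   settlements when the minimum distance between their boundary geometries
   is strictly below d_max = 150 m (touching polygons are always
   connected). An STRtree prunes candidates; the result is identical to the
   all-pairs rule.

## Community detection

Communities of the proximity graph are found per connected component by
recursive spectral bisection of the modularity matrix
B_ij = A_ij − k_i k_j / 2m. For a vertex group g the generalized matrix
B^(g)_ij = B_ij − δ_ij Σ_{l∈g} B_il is formed; the group is split by the
sign of its leading eigenvector, and the split is accepted only when the
leading eigenvalue exceeds 10⁻¹⁰ *and* the modularity gain
ΔQ = sᵀB^(g)s / 4m is strictly positive. Eigenvector entries within
tolerance of zero join the positive side; the eigenvector's arbitrary
global sign is fixed by making its largest-magnitude entry positive, so the
procedure is deterministic. Components of ≤500 vertices use a dense
symmetric eigendecomposition; larger ones use Lanczos iteration with a
fixed start vector.

Each proposed bisection is refined by a vertex-moving pass (each vertex
moved exactly once per sweep, greatest-gain-first, rolling back to the best
intermediate state, sweeps repeated to convergence) before the gain test.
The bare sign split frequently misplaces one or two vertices on small dense
graphs — benchmarked on random connected graphs of ≤8 vertices it reaches
95% of the exhaustive-search maximum modularity on only ~82% of graphs
(igraph's implementation behaves the same, ~83%), while the refined split
reaches it on ~99%. The refinement is part of the spectral method's
published form and is enabled by default; `fine_tune=False` restores the
bare split. Modularity is always evaluated on the unweighted simple graph.

Merging is bookkeeping: one agglomeration per community, geometry the union
of members, population and area the sums, ids assigned by descending
population (ties: smallest member settlement id).

## Urban hierarchy and shares

Agglomerations are classified by population into seven classes with
boundaries 5 k / 20 k / 100 k / 1 M / 10 M / 40 M. All intervals are
half-open with an inclusive lower bound — the source tabulations mix ">"
and ranges, so one convention is fixed and documented; exactly 100,000
people is a Class-1 urban area. Percent urban uses census totals as the
denominator (national: sum of counts; per admin zone: the zone's census
count), so a zone's share can exceed 100% when agglomeration geometry
extends beyond its census support; such rows are flagged, not clipped,
because the artifact is informative.

## Synthetic landscapes

The generator fabricates complete study inputs so every stage is testable
without downloads. True density is a low rural background (default
0.5 persons/ha) plus Gaussian settlement kernels (peak, decay length);
districts are Voronoi regions of randomly chosen cells, dissolved from cell
boxes so rasterization is exact; district counts are the integrated true
surface rounded by largest remainder, so integer counts sum exactly to the
rounded total and conservation tests can be exact. The covariate stack has
a noiseless transform of true log density, a noisy correlate (Gaussian
noise, default sd 0.25), and an irrelevant layer. Uninhabitable cells are
drawn from the low-density half of the landscape (default fraction 0.05)
and carry zero true population.

Two regimes mirror observed settlement patterns: overlapping medium
kernels (coalescent belts) and isolated tall kernels (concentrated cores).
Threshold-monotonicity checks use the isolated regime (kernels ≥1.5 km
apart, decays 150–300 m, peaks 8–40/ha): there, selected area, settlement
count and urban population are all non-increasing in τ. In the coalescent
regime settlement *count* is genuinely non-monotone — lowering τ merges
settlements — which is the expected behaviour, not a defect; area and
population remain monotone in every regime.

Planted-cluster scenes put k clusters of 2–3 dense 3×3-cell blobs
(≈60 persons/ha) on the grid: blobs within a cluster are one cell apart
(100 m < d_max) and clusters at least 600 m apart (> d_max), so the true
settlement-to-agglomeration membership is known by construction. Census
districts are seeded at each blob plus random fill cells (150 districts on
a 120×120 grid), keeping census support fine enough that the
range-restricted forest can still place above-threshold density on blobs.
End-to-end recovery (fit → redistribute → delineate → communities) returns
adjusted Rand index 1.0 on these scenes across seeds.

**What passing tests do not show.** Synthetic covariates are direct
transforms of the truth; real covariates (lights, land cover, terrain) are
noisier and mutually confounded, so real-data OOB fits and per-cell
correlations will be lower than the near-perfect synthetic ones. The
generator has no water bodies, so the known failure mode of
peninsular/island settlements separated by water is not exercised; nor are
boundary-misalignment and census-undercount errors.

## Problem sizes and numerics

Default test and acceptance problem sizes are chosen to exercise each
property at comfortably interactive scale: 50×50–120×120 grids, 15–200
districts, 500-tree forests, 200-graph community benchmarks against
exhaustive search over all partitions of ≤8 vertices. Eigen-solver
tolerance 10⁻¹⁰, modularity-gain threshold 10⁻¹², conservation asserted at
10⁻⁶ relative. All randomness flows through explicit integer seeds;
identical inputs and seed give bit-identical weight and population grids.

## Known limitations

- No reprojection: all inputs must already share one projected metric CRS.
- Raster I/O is ESRI ASCII grid (text, GDAL-readable) rather than GeoTIFF.
- Binary habitability only; no partial-cell masking.
- The proximity graph is unweighted; weighting edges by shared-border
  length is out of scope.
- No temporal modelling: multi-year runs are independent runs per year on
  pre-matched zone boundaries.
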