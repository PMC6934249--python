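# magpie-urban

Tools for measuring urbanization consistently from census counts:
**dasymetric population gridding** plus **metropolitan agglomeration
delineation**.

Official urban/rural statistics depend on administrative definitions that
vary by country and era, which makes urbanization levels incomparable and
hides dense settlement outside city limits. This package implements a
definition that needs only census-unit population counts and gridded
covariates: disaggregate the counts to a ~100 m grid, then call urban
whatever the grid itself says is dense and connected. It is aimed at
spatial demographers and urban researchers who want reproducible,
jurisdiction-free urban delineations and size hierarchies.

## Method

**Stage 1 — gridded population intensity.** A random forest regresses
zone-level log population density, ln(N_z / A_z), on zonal means of
covariate rasters, and is evaluated per cell to give weights
w_i = exp(ŷ_i). Census counts are redistributed within each zone,

    persons_i = N_z · w_i / Σ_{j∈z} w_j ,

so every zone's cells sum exactly to its census count; protected or
uninhabitable cells get zero weight.

**Stage 2 — metropolitan agglomerations.** From the population grid:
select cells with density ≥ τ (default 7.5 persons/ha); group contiguous
selected cells into settlement polygons and fill their holes; drop
fragments under 2 ha; connect settlements whose boundaries lie within
150 m into a proximity graph; partition the graph with Newman's
leading-eigenvector modularity method (Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m]
δ(c_i,c_j)); merge each community into one agglomeration. Agglomerations
are classified into a seven-class size hierarchy (<5 k up to >40 M
"megalopolis") and tabulated into urbanization shares.

A fully synthetic landscape generator (Gaussian settlement kernels,
Voronoi census districts with exactly-consistent integer counts, planted
cluster structure) makes the whole pipeline testable offline.

## Worked example

The `magpie` CLI chains the stages; every command reads and writes plain
text (ESRI ASCII rasters, GeoJSON, CSV).

```
$ magpie synth --out-dir demo --seed 7 --planted
scene written to demo (seed=7, total=11422)

$ magpie disaggregate --zones demo/districts.geojson --counts demo/counts.csv \
    --year 2011 --stack demo/stack --mask demo/mask.asc --out demo/pop.asc --seed 7
population grid written to demo/pop.asc (OOB pseudo-R2 0.977)

$ magpie delineate --pop demo/pop.asc --out-dir demo/delineated
8 settlements -> 3 agglomerations (Q=0.640)

$ magpie summarize --mas demo/delineated/agglomerations.geojson \
    --zones demo/districts.geojson --counts demo/counts.csv --year 2011 \
    --pop demo/pop.asc --out demo/table.csv
urban population 3,377 of 11,422 (29.57% urban)
```

Reading the output: the synthetic scene planted three clusters of dense
settlement blobs in an 11,422-person landscape. The forest explains 97.7%
of out-of-bag variance in zone log density; delineation finds the eight
blobs as settlements and the community step reassembles them into exactly
the three planted agglomerations (partition modularity Q = 0.64). The
summary table (`demo/table.csv`) counts all three in the "< 5k town" class
with 3,377 people — 29.57% of the census population lives at urban density
here. The same stages are available as library functions
(`magpie.disaggregate`, `magpie.delineate`, `magpie.tabulate_hierarchy`).

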