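"""Synthetic landscapes: covariates, true population, districts, planted clusters.

Every other module is testable without any external download because this
module fabricates complete study inputs: a true population-density surface
built from Gaussian settlement kernels over a low background, a covariate
stack correlated with that truth, a binary habitability mask,
Voronoi-of-random-cells census districts with integer counts that integrate
the true surface, and (for delineation tests) planted cluster structure in
which ground-truth settlement-to-agglomeration membership is known by
construction.

Scenes are fully determined by their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from .communities import MetroAgglomeration
from .dasymetric import PopulationGrid
from .grid import CovariateStack, Grid, GridError, Zone, ZoneSet

_CRS = "synthetic-utm"


@dataclass(frozen=True)
class SettlementKernel:
    """One Gaussian settlement: centre (m), peak density (persons/ha), decay (m)."""

    x: float
    y: float
    peak_per_ha: float
    decay_m: float


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a synthetic landscape.

    Defaults describe a 10 km x 10 km landscape of 1-ha cells split into 50
    census districts, with a 0.5 persons/ha rural background — low enough
    that only settlement kernels can cross urban density thresholds.
    """

    shape: tuple[int, int] = (100, 100)
    cell_size_m: float = 100.0
    n_districts: int = 50
    settlements: tuple[SettlementKernel, ...] = ()
    background_density: float = 0.5
    covariate_noise_sd: float = 0.25
    mask_fraction: float = 0.05
    seed: int = 0
    year: int = 2011

    def __post_init__(self) -> None:
        if self.background_density < 0:
            raise GridError("background density must be nonnegative")
        for s in self.settlements:
            if not s.peak_per_ha > self.background_density:
                raise GridError("settlement peaks must exceed the background density")


@dataclass
class SyntheticScene:
    """A generated landscape: truth, covariates, mask, districts, planted labels."""

    spec: SceneSpec
    truth: PopulationGrid
    stack: CovariateStack
    mask: Grid
    zones: ZoneSet
    planted: dict | None = None

    @property
    def year(self) -> int:
        return self.spec.year

    @property
    def total_count(self) -> int:
        return sum(self.zones.counts_for(self.year).values())


def _density_surface(spec: SceneSpec, grid: Grid) -> np.ndarray:
    X, Y = grid.center_mesh()
    dens = np.full(grid.shape, float(spec.background_density))
    xmin, ymin, xmax, ymax = grid.bounds
    for s in spec.settlements:
        if not (xmin <= s.x <= xmax and ymin <= s.y <= ymax):
            raise GridError(f"settlement at ({s.x}, {s.y}) lies outside the grid")
        d2 = (X - s.x) ** 2 + (Y - s.y) ** 2
        dens += s.peak_per_ha * np.exp(-d2 / (2.0 * s.decay_m**2))
    return dens


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative values to integers summing exactly to ``total``."""
    floors = np.floor(values).astype(np.int64)
    remainder = int(total - floors.sum())
    if remainder > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:remainder]] += 1
    elif remainder < 0:  # possible only via pathological inputs; trim largest
        order = np.argsort(values - floors, kind="stable")
        floors[order[:(-remainder)]] -= 1
    return floors


def _district_zones(
    labels: np.ndarray,
    grid: Grid,
    persons: np.ndarray,
    year: int,
) -> ZoneSet:
    """Dissolve per-cell district labels into polygons with integer counts."""
    n = labels.max() + 1
    sums = np.bincount(labels.ravel(), weights=persons.ravel(), minlength=n)
    counts = _largest_remainder(sums, int(round(sums.sum())))
    cs = grid.cell_size_m
    x0, y0 = grid.x_origin, grid.y_origin
    zones = []
    width = len(str(n - 1))
    for d in range(n):
        rows, cols = np.nonzero(labels == d)
        cells = [
            box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
            for r, c in zip(rows, cols)
        ]
        zones.append(
            Zone(
                zone_id=f"D{d:0{width}d}",
                geometry=unary_union(cells),
                counts={year: int(counts[d])},
            )
        )
    return ZoneSet(zones, crs=_CRS)


def _voronoi_labels(
    grid: Grid, seed_cells: np.ndarray
) -> np.ndarray:
    """Assign every cell to its nearest seed cell (ties to the lowest index)."""
    rows, cols = np.unravel_index(seed_cells, grid.shape)
    X, Y = grid.center_mesh()
    sx = grid.x_centers[cols]
    sy = grid.y_centers[rows]
    d2 = (X.ravel()[:, None] - sx[None, :]) ** 2 + (Y.ravel()[:, None] - sy[None, :]) ** 2
    return np.argmin(d2, axis=1).astype(np.int32).reshape(grid.shape)


def _covariates(
    density: np.ndarray, template: Grid, rng: np.random.Generator, noise_sd: float
) -> CovariateStack:
    log_exact = np.log(np.clip(density, 1e-3, None))
    noisy = density + rng.normal(0.0, noise_sd, size=density.shape)
    irrelevant = rng.normal(0.0, 1.0, size=density.shape)
    return CovariateStack(
        {
            "log_density_exact": template.like(log_exact),
            "noisy_correlate": template.like(noisy),
            "irrelevant": template.like(irrelevant),
        }
    )


def generate_landscape(spec: SceneSpec) -> SyntheticScene:
    """Build a complete synthetic scene from a spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    grid = Grid(
        np.zeros(spec.shape), 0.0, rows * spec.cell_size_m, spec.cell_size_m, crs=_CRS
    )
    density = _density_surface(spec, grid)

    # Habitability mask: uninhabitable cells are drawn from the low-density
    # half of the landscape, emulating protected/steep terrain away from towns.
    habitable = np.ones(spec.shape, dtype=bool)
    n_cells = rows * cols
    n_masked = int(spec.mask_fraction * n_cells)
    if n_masked > 0:
        flat = density.ravel()
        candidates = np.nonzero(flat <= np.median(flat))[0]
        chosen = rng.choice(candidates, size=min(n_masked, candidates.size), replace=False)
        habitable.ravel()[chosen] = False
    density = np.where(habitable, density, 0.0)

    persons = density * grid.cell_area_ha
    stack = _covariates(density, grid, rng, spec.covariate_noise_sd)
    mask = grid.like(habitable.astype(np.float64), nodata=-1.0)

    seed_cells = rng.choice(n_cells, size=spec.n_districts, replace=False)
    labels = _voronoi_labels(grid, np.sort(seed_cells))
    zones = _district_zones(labels, grid, persons, spec.year)

    truth = PopulationGrid(grid.like(persons, nodata=-1.0))
    return SyntheticScene(spec=spec, truth=truth, stack=stack, mask=mask, zones=zones)


def random_scene_spec(
    seed: int,
    n_settlements: int = 12,
    shape: tuple[int, int] = (100, 100),
    n_districts: int = 50,
    peak_range: tuple[float, float] = (5.0, 40.0),
    decay_range: tuple[float, float] = (150.0, 600.0),
    min_separation_m: float | None = None,
    **kwargs,
) -> SceneSpec:
    """Draw a random but reproducible SceneSpec (kernels inside the grid).

    ``min_separation_m`` rejection-samples kernel centres until they are
    pairwise at least that far apart, producing the isolated
    concentrated-core regime; the default (None) allows overlapping kernels,
    the coalescent regime.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    cell = kwargs.get("cell_size_m", 100.0)
    centres: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(centres) == n_settlements:
            break
        x = float(rng.uniform(0.1, 0.9) * cols * cell)
        y = float(rng.uniform(0.1, 0.9) * rows * cell)
        if min_separation_m is not None and any(
            (x - cx) ** 2 + (y - cy) ** 2 < min_separation_m**2 for cx, cy in centres
        ):
            continue
        centres.append((x, y))
    if len(centres) < n_settlements:
        raise GridError("could not place settlements at the requested separation")
    settlements = tuple(
        SettlementKernel(
            x=cx,
            y=cy,
            peak_per_ha=float(rng.uniform(*peak_range)),
            decay_m=float(rng.uniform(*decay_range)),
        )
        for cx, cy in centres
    )
    return SceneSpec(
        shape=shape,
        n_districts=n_districts,
        settlements=settlements,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Planted-cluster scenes
# ---------------------------------------------------------------------------

_BLOB_CELLS = 3  # each settlement blob is a 3x3-cell square


def generate_planted_clusters(
    k_clusters: int = 3,
    *,
    shape: tuple[int, int] = (120, 120),
    cell_size_m: float = 100.0,
    n_districts: int = 150,
    gap_m: float = 600.0,
    d_max_m: float = 150.0,
    blob_density: float = 60.0,
    background_density: float = 0.5,
    covariate_noise_sd: float = 0.25,
    seed: int = 0,
    year: int = 2011,
) -> SyntheticScene:
    """Scene with k planted agglomerations of known settlement membership.

    Each cluster is a short chain of 2-3 dense 3x3-cell blobs separated by a
    one-cell gap (100 m < d_max, so the proximity graph connects them), and
    clusters are separated by at least ``gap_m`` (> d_max, so they occupy
    different graph components).  The delineation pipeline at the default
    thresholds should therefore recover exactly k agglomerations whose blob
    membership matches the planted truth.
    """
    if not gap_m > d_max_m:
        raise GridError("inter-cluster gap must exceed the graph distance threshold")
    if not cell_size_m < d_max_m:
        raise GridError("within-cluster spacing (one cell) must be below d_max")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    cs = cell_size_m

    max_blobs = 3
    ext_cells = max_blobs * _BLOB_CELLS + (max_blobs - 1)  # chain length in cells
    gap_cells = int(math.ceil(gap_m / cs))
    tile = ext_cells + gap_cells
    tiles_r = rows // tile
    tiles_c = cols // tile
    if tiles_r * tiles_c < k_clusters:
        raise GridError("infeasible packing: grid too small for requested clusters")

    tile_ids = rng.choice(tiles_r * tiles_c, size=k_clusters, replace=False)
    density = np.full(shape, float(background_density))
    blob_centers: list[tuple[float, float]] = []
    blob_cluster: list[int] = []

    grid = Grid(np.zeros(shape), 0.0, rows * cs, cs, crs=_CRS)
    blob_seed_cells: list[int] = []
    for cluster_id, t in enumerate(np.sort(tile_ids)):
        tr, tc = divmod(int(t), tiles_c)
        r0 = tr * tile
        c0 = tc * tile
        n_blobs = int(rng.integers(2, max_blobs + 1))
        horizontal = bool(rng.integers(0, 2))
        # chain of n_blobs 3x3 blobs with one-cell gaps, inside this tile
        for b in range(n_blobs):
            off = b * (_BLOB_CELLS + 1)
            br = r0 + (0 if horizontal else off)
            bc = c0 + (off if horizontal else 0)
            level = blob_density * float(rng.uniform(0.9, 1.1))
            density[br : br + _BLOB_CELLS, bc : bc + _BLOB_CELLS] = level
            cr, cc = br + 1, bc + 1  # centre cell of the 3x3 blob
            blob_centers.append((grid.x_centers[cc], grid.y_centers[cr]))
            blob_cluster.append(cluster_id)
            blob_seed_cells.append(cr * cols + cc)

    persons = density * grid.cell_area_ha
    stack = _covariates(density, grid, rng, covariate_noise_sd)
    mask = grid.like(np.ones(shape), nodata=-1.0)

    # Census districts: one seed per blob (census units follow settlements)
    # plus random fill seeds elsewhere.
    n_fill = n_districts - len(blob_seed_cells)
    if n_fill <= 0:
        raise GridError("n_districts must exceed the number of planted blobs")
    free = np.setdiff1d(np.arange(rows * cols), np.array(blob_seed_cells))
    fill = rng.choice(free, size=n_fill, replace=False)
    seeds = np.sort(np.concatenate([np.array(blob_seed_cells), fill]))
    labels = _voronoi_labels(grid, seeds)
    zones = _district_zones(labels, grid, persons, year)

    spec = SceneSpec(
        shape=shape,
        cell_size_m=cs,
        n_districts=n_districts,
        settlements=(),
        background_density=background_density,
        covariate_noise_sd=covariate_noise_sd,
        mask_fraction=0.0,
        seed=seed,
        year=year,
    )
    truth = PopulationGrid(grid.like(persons, nodata=-1.0))
    planted = {
        "blob_centers": blob_centers,
        "blob_cluster": blob_cluster,
        "k_clusters": k_clusters,
        "blob_density": blob_density,
    }
    return SyntheticScene(
        spec=spec, truth=truth, stack=stack, mask=mask, zones=zones, planted=planted
    )


def planted_vs_recovered(
    scene: SyntheticScene, mas: list[MetroAgglomeration]
) -> tuple[list[int], list[int]]:
    """Planted and recovered labels per blob, for external-index comparison.

    Each blob's recovered label is the id of the agglomeration whose
    geometry covers the blob centre; blobs covered by no agglomeration get
    a unique negative label (each counts as its own miss).
    """
    if scene.planted is None:
        raise GridError("scene has no planted truth")
    true_labels = list(scene.planted["blob_cluster"])
    found: list[int] = []
    for i, (x, y) in enumerate(scene.planted["blob_centers"]):
        label = -(i + 1)
        for ma in mas:
            if shapely.intersects_xy(ma.geometry, x, y):
                label = ma.ma_id
                break
        found.append(label)
    return true_labels, found
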