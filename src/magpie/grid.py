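"""Raster/vector data model and the zonal operations shared by every stage.

A :class:`Grid` is a single-band raster: a 2-D value array plus a north-up,
square-cell georeference in one projected metric coordinate system.  It is
the universal carrier in this package — covariates, dasymetric weights and
population surfaces are all Grids on one shared georeference.  A
:class:`ZoneSet` holds the census-unit polygons with their per-year counts;
a :class:`CovariateStack` is an ordered set of co-registered Grids.

All point-in-polygon decisions use the cell-centre rule: a cell belongs to a
zone when its centre lies inside (or on the boundary of) the zone polygon.
A centre sitting exactly on a shared zone boundary is assigned to the zone
with the lexicographically smallest id, so zonal statistics and dasymetric
redistribution always agree on cell membership.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

NODATA_DEFAULT = -9999.0


class GridError(ValueError):
    """Raised for georeference mismatches and invalid raster inputs."""


@dataclass
class Grid:
    """Single-band raster with a north-up square-cell metric georeference.

    Parameters
    ----------
    values
        2-D array, row 0 at the northern edge.
    x_origin, y_origin
        Coordinates of the top-left (north-west) corner in metres.
    cell_size_m
        Cell edge length in metres (cells are square and axis-aligned).
    crs
        Opaque identifier of the projected metric CRS; grids only interact
        when their identifiers match.
    nodata
        Sentinel for missing cells; NaN values are also treated as missing.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size_m: float
    crs: str = "metric"
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridError("Grid values must be a 2-D array")
        if not self.cell_size_m > 0:
            raise GridError("cell_size_m must be positive")
        if not self.crs:
            raise GridError("Grid requires a CRS identifier")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m**2 / 10_000.0

    @property
    def x_centers(self) -> np.ndarray:
        n_cols = self.shape[1]
        return self.x_origin + (np.arange(n_cols) + 0.5) * self.cell_size_m

    @property
    def y_centers(self) -> np.ndarray:
        n_rows = self.shape[0]
        return self.y_origin - (np.arange(n_rows) + 0.5) * self.cell_size_m

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of every cell-centre coordinate, shaped like values."""
        return np.meshgrid(self.x_centers, self.y_centers)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        rows, cols = self.shape
        return (
            self.x_origin,
            self.y_origin - rows * self.cell_size_m,
            self.x_origin + cols * self.cell_size_m,
            self.y_origin,
        )

    # -- values ------------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        vals = self.values
        mask = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask &= ~np.isnan(vals)
        return mask

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New Grid sharing this georeference."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise GridError("replacement values must match grid shape")
        return Grid(
            values,
            self.x_origin,
            self.y_origin,
            self.cell_size_m,
            crs=self.crs,
            nodata=self.nodata if nodata is None else nodata,
        )

    def copy(self) -> "Grid":
        return dataclasses.replace(self, values=self.values.copy())

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size_m, other.cell_size_m)
        )


@dataclass
class Zone:
    """One census unit: stable id, polygon geometry, per-year counts."""

    zone_id: str
    geometry: BaseGeometry
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 10_000.0


@dataclass
class ZoneSet:
    """Non-overlapping census polygons with population counts per year."""

    zones: list[Zone]
    crs: str = "metric"

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise GridError("zone_ids must be unique")
        for z in self.zones:
            if not z.geometry.is_valid:
                raise GridError(f"zone {z.zone_id!r} has invalid geometry")
            for year, count in z.counts.items():
                if count < 0:
                    raise GridError(f"zone {z.zone_id!r} has negative count for {year}")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self) -> Iterator[Zone]:
        return iter(self.zones)

    @property
    def ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]

    def get(self, zone_id: str) -> Zone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    def counts_for(self, year: int) -> dict[str, int]:
        out = {}
        for z in self.zones:
            if year not in z.counts:
                raise GridError(f"zone {z.zone_id!r} has no count for year {year}")
            out[z.zone_id] = z.counts[year]
        return out


@dataclass
class CovariateStack:
    """Ordered, co-registered covariate rasters keyed by name."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise GridError("CovariateStack requires at least one layer")
        grids = list(self.layers.values())
        template = grids[0]
        for name, g in self.layers.items():
            if not template.same_georef(g):
                raise GridError(f"layer {name!r} does not share the stack georeference")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def resample_nearest(src: Grid, target: Grid) -> Grid:
    """Nearest-neighbour resample of ``src`` onto ``target``'s georeference.

    Each output cell takes the value of the source cell containing the output
    cell's centre.  Output cells whose centre falls outside the source extent
    become nodata; source nodata propagates.
    """
    if not src.crs or not target.crs:
        raise GridError("both grids need a CRS identifier")
    if src.crs != target.crs:
        raise GridError(f"CRS mismatch: {src.crs!r} vs {target.crs!r}")

    xs = target.x_centers
    ys = target.y_centers
    cols = np.floor((xs - src.x_origin) / src.cell_size_m).astype(int)
    rows = np.floor((src.y_origin - ys) / src.cell_size_m).astype(int)
    col_ok = (cols >= 0) & (cols < src.shape[1])
    row_ok = (rows >= 0) & (rows < src.shape[0])
    if not (col_ok.any() and row_ok.any()):
        raise GridError("no spatial overlap between source and target extents")

    out = np.full(target.shape, src.nodata, dtype=np.float64)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = row_ok[:, None] & col_ok[None, :]
    out[inside] = src.values[rr[inside], cc[inside]]
    return Grid(
        out,
        target.x_origin,
        target.y_origin,
        target.cell_size_m,
        crs=target.crs,
        nodata=src.nodata,
    )


def rasterize_zones(zones: ZoneSet, grid: Grid) -> tuple[np.ndarray, list[str]]:
    """Label every cell with the index of the zone containing its centre.

    Returns ``(labels, ordered_ids)`` where ``labels`` holds -1 for cells in
    no zone and otherwise an index into ``ordered_ids`` (sorted zone ids).
    Zones are scanned in ascending id order and a cell is never reassigned,
    which implements the smallest-id tie-break for centres on shared
    boundaries.
    """
    if len(zones) == 0:
        raise GridError("empty ZoneSet")
    if zones.crs != grid.crs:
        raise GridError(f"CRS mismatch: zones {zones.crs!r} vs grid {grid.crs!r}")
    labels = np.full(grid.shape, -1, dtype=np.int32)
    ordered = sorted(zones, key=lambda z: z.zone_id)
    xs, ys = grid.x_centers, grid.y_centers
    cs = grid.cell_size_m
    for idx, zone in enumerate(ordered):
        minx, miny, maxx, maxy = zone.geometry.bounds
        c0 = max(0, int(np.floor((minx - grid.x_origin) / cs - 0.5)))
        c1 = min(grid.shape[1], int(np.ceil((maxx - grid.x_origin) / cs + 0.5)))
        r0 = max(0, int(np.floor((grid.y_origin - maxy) / cs - 0.5)))
        r1 = min(grid.shape[0], int(np.ceil((grid.y_origin - miny) / cs + 0.5)))
        if c0 >= c1 or r0 >= r1:
            continue
        X, Y = np.meshgrid(xs[c0:c1], ys[r0:r1])
        hit = shapely.intersects_xy(zone.geometry, X.ravel(), Y.ravel())
        hit = hit.reshape(X.shape)
        window = labels[r0:r1, c0:c1]
        window[(window == -1) & hit] = idx
    return labels, [z.zone_id for z in ordered]


def zonal_mean(grid: Grid, zones: ZoneSet) -> dict[str, float]:
    """Mean of valid grid values over cell centres inside each zone.

    Zones containing no valid cell centre map to NaN.
    """
    labels, ids = rasterize_zones(zones, grid)
    valid = grid.valid_mask & (labels >= 0)
    lab = labels[valid]
    vals = grid.values[valid].astype(np.float64)
    sums = np.bincount(lab, weights=vals, minlength=len(ids))
    counts = np.bincount(lab, minlength=len(ids))
    out: dict[str, float] = {}
    for i, zid in enumerate(ids):
        out[zid] = sums[i] / counts[i] if counts[i] > 0 else float("nan")
    return out


def signed_distance_to_class_edge(class_grid: Grid, target_class: int) -> Grid:
    """Signed Euclidean distance (m) to the nearest cell of opposite class.

    Distances are centre-to-centre.  Cells of the target class get negative
    sign (inside the class), all other valid cells positive.  Nodata cells
    take part in neither class and stay nodata.
    """
    valid = class_grid.valid_mask
    target = valid & (class_grid.values == target_class)
    other = valid & ~target
    if not target.any() or not other.any():
        raise GridError("no class edge present")
    cs = class_grid.cell_size_m
    # EDT measures distance to the nearest zero pixel, i.e. to the complement.
    dist_to_target = ndimage.distance_transform_edt(~target) * cs
    dist_to_other = ndimage.distance_transform_edt(~other) * cs
    out = np.where(target, -dist_to_other, dist_to_target)
    out[~valid] = class_grid.nodata
    return class_grid.like(out)
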