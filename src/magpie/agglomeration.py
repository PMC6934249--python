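"""Settlement delineation: threshold, region grouping, holes, area filter, graph.

Stages (on a population grid): select cells at or above a density threshold
(default 7.5 persons/ha), group contiguous selected cells into settlement
polygons (rook contiguity by default), remove interior holes so enclosed
parks/hills/lakes count as part of the urban area, drop fragments below a
minimum area (default 2 ha, about two cells), integrate population over the
hole-filled extent, and finally connect settlements whose boundaries lie
within a distance threshold (default 150 m, roughly one skipped cell
diagonal) into a proximity graph for community detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .dasymetric import PopulationGrid
from .grid import Grid, GridError


@dataclass
class SettlementPolygon:
    """A contiguous above-threshold settlement, hole-filled, with population."""

    settlement_id: int
    geometry: BaseGeometry
    area_ha: float
    population: float
    cell_count: int


def threshold_cells(
    pop: PopulationGrid, tau_per_ha: float, strict: bool = False
) -> Grid:
    """Binary grid of cells whose density meets the threshold.

    Selection is inclusive (``density >= tau``) by default; ``strict=True``
    switches to a strict ``>``.  Nodata cells are never selected.
    """
    if not tau_per_ha > 0:
        raise GridError("density threshold must be positive")
    dens = pop.density
    valid = dens.valid_mask
    if strict:
        sel = valid & (dens.values > tau_per_ha)
    else:
        sel = valid & (dens.values >= tau_per_ha)
    return dens.like(sel.astype(np.uint8), nodata=255)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def label_regions(
    binary: Grid, connectivity: int = 4
) -> tuple[np.ndarray, list[BaseGeometry]]:
    """Connected components of selected cells, each dissolved into a polygon.

    Returns the label raster (0 = background) and one geometry per region,
    ordered by label.  Labels follow the row-major scan, so region 1 is the
    component whose first cell appears top-left-most — a deterministic
    numbering.  With rook (4) contiguity each region is a single polygon;
    with queen (8) contiguity corner-touching parts form one region whose
    geometry may be a MultiPolygon.
    """
    if connectivity not in _STRUCTURES:
        raise GridError("connectivity must be 4 or 8")
    selected = (binary.values == 1) & binary.valid_mask
    labels, n = ndimage.label(selected, structure=_STRUCTURES[connectivity])
    polygons: list[BaseGeometry] = []
    cs = binary.cell_size_m
    x0, y0 = binary.x_origin, binary.y_origin
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        cells = [
            box(
                x0 + c * cs,
                y0 - (r + 1) * cs,
                x0 + (c + 1) * cs,
                y0 - r * cs,
            )
            for r, c in zip(rows, cols)
        ]
        polygons.append(unary_union(cells))
    return labels, polygons


def fill_holes(polys: list[BaseGeometry]) -> list[BaseGeometry]:
    """Replace each polygon by its exterior ring(s) only.

    Enclosed below-threshold pockets become part of the settlement; area
    never decreases and each input geometry is contained in its output.
    """
    out: list[BaseGeometry] = []
    for geom in polys:
        if not geom.is_valid:
            raise GridError("invalid geometry passed to fill_holes")
        if isinstance(geom, Polygon):
            out.append(Polygon(geom.exterior))
        elif isinstance(geom, MultiPolygon):
            filled = [Polygon(p.exterior) for p in geom.geoms]
            out.append(unary_union(filled))
        else:
            raise GridError(f"cannot fill holes of geometry type {geom.geom_type}")
    return out


def filter_min_area(
    polys: list[BaseGeometry], min_area_ha: float = 2.0
) -> list[BaseGeometry]:
    """Drop polygons strictly below the minimum area (hectares)."""
    return [p for p in polys if p.area / 10_000.0 >= min_area_ha]


def integrate_population(
    polys: list[BaseGeometry], pop: PopulationGrid
) -> list[SettlementPolygon]:
    """Attach population and area to each (hole-filled) settlement polygon.

    Population is the sum of persons at cells whose centres fall inside the
    geometry — including formerly below-threshold cells inside filled holes.
    Settlement ids are 1-based in the order given (the deterministic
    label order when coming from :func:`label_regions`).
    """
    grid = pop.persons
    xs, ys = grid.x_centers, grid.y_centers
    cs = grid.cell_size_m
    out: list[SettlementPolygon] = []
    for i, geom in enumerate(polys, start=1):
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int(np.floor((minx - grid.x_origin) / cs)))
        c1 = min(grid.shape[1], int(np.ceil((maxx - grid.x_origin) / cs)))
        r0 = max(0, int(np.floor((grid.y_origin - maxy) / cs)))
        r1 = min(grid.shape[0], int(np.ceil((grid.y_origin - miny) / cs)))
        population = 0.0
        cell_count = 0
        if c0 < c1 and r0 < r1:
            X, Y = np.meshgrid(xs[c0:c1], ys[r0:r1])
            hit = shapely.intersects_xy(geom, X.ravel(), Y.ravel()).reshape(X.shape)
            window = grid.values[r0:r1, c0:c1]
            valid = grid.valid_mask[r0:r1, c0:c1]
            inside = hit & valid
            population = float(window[inside].sum())
            cell_count = int(inside.sum())
        out.append(
            SettlementPolygon(
                settlement_id=i,
                geometry=geom,
                area_ha=geom.area / 10_000.0,
                population=population,
                cell_count=cell_count,
            )
        )
    return out


def build_proximity_graph(
    settlements: list[SettlementPolygon], d_max_m: float = 150.0
) -> nx.Graph:
    """Graph with one vertex per settlement; edges join boundaries closer than d_max.

    The edge rule is a strict inequality (distance < d_max), so two polygons
    separated by exactly d_max are not connected; touching or overlapping
    polygons (distance 0) always are.  An STRtree prunes candidate pairs but
    the result equals the all-pairs minimum-distance rule.
    """
    g = nx.Graph()
    for s in settlements:
        g.add_node(s.settlement_id)
    if not settlements:
        return g
    geoms = [s.geometry for s in settlements]
    ids = [s.settlement_id for s in settlements]
    tree = STRtree(geoms)
    # dwithin uses <=; the strict rule is re-checked with an exact distance.
    pairs = tree.query(geoms, predicate="dwithin", distance=d_max_m)
    for i, j in pairs.T:
        if i < j and geoms[int(i)].distance(geoms[int(j)]) < d_max_m:
            g.add_edge(ids[int(i)], ids[int(j)])
    return g
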