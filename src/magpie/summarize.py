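"""Urban hierarchy classification, tabulation and urbanization shares.

Size classes follow the Indian census-style hierarchy with an extra top
class for agglomerations above 40 million people.  All class intervals are
half-open [lo, hi) with an inclusive lower bound, so e.g. exactly 100,000
people is a Class-1 urban area.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .communities import MetroAgglomeration
from .dasymetric import PopulationGrid
from .grid import GridError, ZoneSet, rasterize_zones


class SizeClass(enum.IntEnum):
    """Ordered urban size hierarchy; values index ascending boundaries."""

    LT5K = 0              # < 5,000 town
    T5_20K = 1            # 5,000 - 20,000 town
    T20_100K = 2          # 20,000 - 100,000 town
    CLASS1_100K_1M = 3    # Class 1 urban area, 100k - 1M
    MILLION_1_10M = 4     # million-plus urban area, 1M - 10M
    MEGACITY_10_40M = 5   # megacity, 10M - 40M
    MEGALOPOLIS_GT40M = 6 # megalopolis, > 40M

    @property
    def label(self) -> str:
        return _LABELS[self]


_BOUNDS = [0.0, 5e3, 2e4, 1e5, 1e6, 1e7, 4e7, np.inf]

_LABELS = {
    SizeClass.LT5K: "< 5k town",
    SizeClass.T5_20K: "5-20k town",
    SizeClass.T20_100K: "20-100k town",
    SizeClass.CLASS1_100K_1M: "Class 1 urban area (100k-1 million)",
    SizeClass.MILLION_1_10M: "Million+ urban area (1-10 million)",
    SizeClass.MEGACITY_10_40M: "Megacity (10-40 million)",
    SizeClass.MEGALOPOLIS_GT40M: "Megalopolis (> 40 million)",
}


def classify_size(population: float) -> SizeClass:
    """Map a population to its size class (lower bound inclusive)."""
    if population < 0:
        raise GridError("population must be nonnegative")
    idx = int(np.searchsorted(_BOUNDS, population, side="right")) - 1
    return SizeClass(min(idx, len(SizeClass) - 1))


@dataclass
class SummaryTable:
    """Counts and populations per size class plus the urbanization share."""

    per_class: pd.DataFrame  # index: SizeClass label, columns: count, population
    urban_population: float
    total_population: float

    @property
    def percent_urban(self) -> float:
        return 100.0 * self.urban_population / self.total_population


def tabulate_hierarchy(
    mas: list[MetroAgglomeration], total_population: float
) -> SummaryTable:
    """Tabulate the urban hierarchy and the national urbanization share.

    ``total_population`` is the census total for the year (the denominator
    of percent urban); class populations always sum to the urban total.
    """
    if total_population <= 0:
        raise GridError("total_population must be positive")
    counts = {sc: 0 for sc in SizeClass}
    pops = {sc: 0.0 for sc in SizeClass}
    for ma in mas:
        sc = classify_size(ma.population)
        counts[sc] += 1
        pops[sc] += ma.population
    order = list(reversed(SizeClass))  # largest class first, Table-style
    per_class = pd.DataFrame(
        {
            "count": [counts[sc] for sc in order],
            "population": [pops[sc] for sc in order],
        },
        index=pd.Index([sc.label for sc in order], name="size_class"),
    )
    urban = float(per_class["population"].sum())
    return SummaryTable(per_class, urban, float(total_population))


def admin_overlay_share(
    mas: list[MetroAgglomeration],
    admin_zones: ZoneSet,
    pop: PopulationGrid,
    year: int,
) -> pd.DataFrame:
    """Urban population and urbanization share per administrative zone.

    A cell is urban when its centre lies inside any agglomeration geometry;
    its persons accrue to the admin zone containing the centre.  The share
    denominator is the zone's census count, so shares can exceed 100% when
    agglomeration extents reach beyond a zone's census support — such rows
    are flagged rather than clipped.
    """
    grid = pop.persons
    labels, ids = rasterize_zones(admin_zones, grid)
    counts = admin_zones.counts_for(year)

    urban_mask = np.zeros(grid.shape, dtype=bool)
    if mas:
        union = unary_union([ma.geometry for ma in mas])
        X, Y = grid.center_mesh()
        urban_mask = shapely.intersects_xy(union, X.ravel(), Y.ravel()).reshape(grid.shape)

    rows = []
    for idx, zid in enumerate(ids):
        in_zone = labels == idx
        urban_pop = float(grid.values[in_zone & urban_mask & grid.valid_mask].sum())
        total = float(counts[zid])
        share = 100.0 * urban_pop / total if total > 0 else float("nan")
        rows.append(
            {
                "zone_id": zid,
                "urban_population": urban_pop,
                "census_population": total,
                "percent_urban": share,
                "flagged_over_100": bool(share > 100.0) if total > 0 else False,
            }
        )
    return pd.DataFrame(rows).set_index("zone_id")
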