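"""Plain-text I/O: ESRI ASCII rasters, GeoJSON vectors, CSV tables.

Rasters are read and written as ESRI ASCII grid (.asc) — a single-band text
format with an explicit nodata tag, readable by GDAL/QGIS.  The CRS
identifier travels in an optional ``.prj`` sidecar holding the identifier
string verbatim.  Zone polygons are GeoJSON FeatureCollections with a
``zone_id`` property; counts live in a CSV keyed by zone_id with one column
per year.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .communities import MetroAgglomeration, Partition
from .agglomeration import SettlementPolygon
from .grid import CovariateStack, Grid, GridError, Zone, ZoneSet


# -- rasters ----------------------------------------------------------------


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    rows, cols = grid.shape
    yll = grid.y_origin - rows * grid.cell_size_m
    with path.open("w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size_m!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, grid.values, fmt="%.10g")
    if grid.crs:
        path.with_suffix(".prj").write_text(grid.crs + "\n")


def read_ascii_grid(path: str | Path, crs: str | None = None) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (rows, cols):
        raise GridError(f"{path}: data shape {values.shape} != header ({rows}, {cols})")
    if crs is None:
        prj = path.with_suffix(".prj")
        crs = prj.read_text().strip() if prj.exists() else "metric"
    cell = header["cellsize"]
    return Grid(
        values,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * cell,
        cell_size_m=cell,
        crs=crs,
        nodata=header.get("nodata_value", -9999.0),
    )


def read_covariate_stack(directory: str | Path, crs: str | None = None) -> CovariateStack:
    """All .asc files of a directory as one stack, keyed by file stem."""
    directory = Path(directory)
    layers = {}
    for path in sorted(directory.glob("*.asc")):
        layers[path.stem] = read_ascii_grid(path, crs=crs)
    if not layers:
        raise GridError(f"no .asc rasters found in {directory}")
    return CovariateStack(layers)


# -- zones ------------------------------------------------------------------


def write_zones_geojson(zones: ZoneSet, path: str | Path) -> None:
    features = []
    for z in zones:
        features.append(
            {
                "type": "Feature",
                "properties": {"zone_id": z.zone_id},
                "geometry": mapping(z.geometry),
            }
        )
    payload = {
        "type": "FeatureCollection",
        "crs_id": zones.crs,
        "features": features,
    }
    Path(path).write_text(json.dumps(payload))


def read_zones_geojson(
    path: str | Path,
    counts_csv: str | Path | None = None,
    crs: str | None = None,
) -> ZoneSet:
    payload = json.loads(Path(path).read_text())
    counts: dict[str, dict[int, int]] = {}
    if counts_csv is not None:
        table = pd.read_csv(counts_csv, dtype={"zone_id": str}).set_index("zone_id")
        for zid, row in table.iterrows():
            counts[zid] = {int(year): int(v) for year, v in row.items()}
    zones = []
    for feat in payload["features"]:
        zid = str(feat["properties"]["zone_id"])
        zones.append(Zone(zid, shape(feat["geometry"]), counts.get(zid, {})))
    return ZoneSet(zones, crs=crs or payload.get("crs_id", "metric"))


def write_counts_csv(zones: ZoneSet, path: str | Path) -> None:
    years = sorted({y for z in zones for y in z.counts})
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["zone_id", *years])
        for z in sorted(zones, key=lambda z: z.zone_id):
            writer.writerow([z.zone_id, *[z.counts.get(y, "") for y in years]])


# -- delineation outputs ----------------------------------------------------


def write_settlements_geojson(
    settlements: list[SettlementPolygon], path: str | Path, crs: str = "metric"
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "settlement_id": s.settlement_id,
                "area_ha": s.area_ha,
                "population": s.population,
                "cell_count": s.cell_count,
            },
            "geometry": mapping(s.geometry),
        }
        for s in settlements
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "crs_id": crs, "features": features})
    )


def write_agglomerations_geojson(
    mas: list[MetroAgglomeration], path: str | Path, crs: str = "metric"
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "ma_id": ma.ma_id,
                "population": ma.population,
                "area_ha": ma.area_ha,
                "density_per_ha": ma.density_per_ha,
                "size_class": getattr(ma.size_class, "name", None),
                "member_ids": ma.member_ids,
            },
            "geometry": mapping(ma.geometry),
        }
        for ma in mas
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "crs_id": crs, "features": features})
    )


def read_agglomerations_geojson(path: str | Path) -> list[MetroAgglomeration]:
    from .summarize import SizeClass

    payload = json.loads(Path(path).read_text())
    mas = []
    for feat in payload["features"]:
        props = feat["properties"]
        sc = props.get("size_class")
        mas.append(
            MetroAgglomeration(
                ma_id=int(props["ma_id"]),
                member_ids=list(props["member_ids"]),
                geometry=shape(feat["geometry"]),
                population=float(props["population"]),
                area_ha=float(props["area_ha"]),
                size_class=SizeClass[sc] if sc else None,
            )
        )
    return mas


def write_graph_csv(graph, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["settlement_a", "settlement_b"])
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            writer.writerow([u, v])


def write_partition_csv(partition: Partition, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["settlement_id", "community"])
        for sid in sorted(partition.membership):
            writer.writerow([sid, partition.membership[sid]])
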