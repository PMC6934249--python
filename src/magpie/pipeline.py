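"""End-to-end drivers: disaggregate counts to a grid, delineate agglomerations."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .agglomeration import (
    SettlementPolygon,
    build_proximity_graph,
    fill_holes,
    filter_min_area,
    integrate_population,
    label_regions,
    threshold_cells,
)
from .communities import (
    MetroAgglomeration,
    Partition,
    detect_communities,
    merge_into_agglomerations,
)
from .dasymetric import (
    DensityModel,
    PopulationGrid,
    WeightSurface,
    build_feature_table,
    fit_density_model,
    predict_weight_surface,
    redistribute,
)
from .grid import CovariateStack, Grid, ZoneSet
from .summarize import classify_size


@dataclass
class DisaggregationResult:
    population: PopulationGrid
    model: DensityModel
    weights: WeightSurface


def disaggregate(
    zones: ZoneSet,
    stack: CovariateStack,
    mask: Grid,
    year: int,
    n_trees: int = 500,
    seed: int = 0,
    zero_count_epsilon: float = 0.5,
) -> DisaggregationResult:
    """Census counts -> gridded population: fit, predict weights, redistribute."""
    table = build_feature_table(zones, stack, year, zero_count_epsilon)
    model = fit_density_model(table, n_trees=n_trees, seed=seed)
    weights = predict_weight_surface(model, stack, mask)
    population = redistribute(weights, zones, year)
    return DisaggregationResult(population, model, weights)


@dataclass
class DelineationResult:
    settlements: list[SettlementPolygon]
    graph: nx.Graph
    partition: Partition
    agglomerations: list[MetroAgglomeration]


def delineate(
    pop: PopulationGrid,
    tau_per_ha: float = 7.5,
    d_max_m: float = 150.0,
    min_area_ha: float = 2.0,
    connectivity: int = 4,
    strict_threshold: bool = False,
) -> DelineationResult:
    """Population grid -> metropolitan agglomerations (threshold .. merge)."""
    binary = threshold_cells(pop, tau_per_ha, strict=strict_threshold)
    _, polygons = label_regions(binary, connectivity=connectivity)
    polygons = fill_holes(polygons)
    polygons = filter_min_area(polygons, min_area_ha)
    settlements = integrate_population(polygons, pop)
    graph = build_proximity_graph(settlements, d_max_m)
    partition = detect_communities(graph)
    mas = merge_into_agglomerations(settlements, partition, classify_size)
    return DelineationResult(settlements, graph, partition, mas)
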