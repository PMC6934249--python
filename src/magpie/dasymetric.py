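"""Random-forest dasymetric disaggregation of census counts to a fine grid.

The model follows the standard top-down gridded-population recipe: fit a
random-forest regression of natural-log population density (persons per
hectare) on zonal covariate means at the census-unit level, predict that
model at every grid cell to obtain a relative weight surface
``w = exp(log-density)``, then redistribute each unit's census count over
its cells proportionally to the weights.  Redistribution conserves the
census count of every unit exactly (up to floating-point round-off), which
is the defining property of dasymetric mapping.

Units here: densities are persons per hectare and one nominal cell is
100 m x 100 m = 1 ha, so cell population and cell density coincide at the
nominal resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .grid import CovariateStack, Grid, GridError, ZoneSet, rasterize_zones, zonal_mean

import pandas as pd


@dataclass
class DensityModel:
    """Fitted random-forest log-density model with out-of-bag diagnostics.

    ``oob_pseudo_r2`` is 1 - OOB-MSE / Var(response): the fraction of
    response variance explained when each zone is predicted only by trees
    that did not sample it (~37% of trees for each zone in expectation).
    """

    regressor: RandomForestRegressor
    covariate_names: list[str]
    n_trees: int
    oob_mse: float
    oob_pseudo_r2: float
    seed: int
    response_range: tuple[float, float] = (0.0, 0.0)

    def predict_log_density(self, X: np.ndarray) -> np.ndarray:
        return self.regressor.predict(X)

    @property
    def importances(self) -> dict[str, float]:
        return dict(zip(self.covariate_names, self.regressor.feature_importances_))


@dataclass
class WeightSurface:
    """Nonnegative per-cell dasymetric weights, zero on uninhabitable cells."""

    weights: Grid
    habitable: np.ndarray  # boolean, True where redistribution may place people
    provenance: str = ""

    def __post_init__(self) -> None:
        w = self.weights.values
        if not np.all(np.isfinite(w)):
            raise GridError("weights must be finite")
        if (w < 0).any():
            raise GridError("weights must be nonnegative")
        if w[~self.habitable].any():
            raise GridError("weights must be zero on masked cells")


@dataclass
class PopulationGrid:
    """Per-cell person counts whose zone sums equal the census counts."""

    persons: Grid

    def __post_init__(self) -> None:
        vals = self.persons.values
        valid = self.persons.valid_mask
        if (vals[valid] < 0).any():
            raise GridError("person counts must be nonnegative")

    @property
    def density(self) -> Grid:
        """Persons per hectare view of the same surface."""
        dens = np.where(
            self.persons.valid_mask,
            self.persons.values / self.persons.cell_area_ha,
            self.persons.nodata,
        )
        return self.persons.like(dens)

    @property
    def total(self) -> float:
        return float(self.persons.values[self.persons.valid_mask].sum())


def build_feature_table(
    zones: ZoneSet,
    stack: CovariateStack,
    year: int,
    zero_count_epsilon: float = 0.5,
) -> pd.DataFrame:
    """Zone-level design table: log density response plus zonal covariate means.

    The response is ``ln(count / area_ha)``; zones with a zero count use a
    pseudo-count of ``zero_count_epsilon`` persons so the log stays finite
    and the census support stays complete.
    """
    counts = zones.counts_for(year)
    rows = {}
    for zone in zones:
        if zone.area_ha <= 0:
            raise GridError(f"zone {zone.zone_id!r} has zero area")
        count = counts[zone.zone_id]
        effective = count if count > 0 else zero_count_epsilon
        rows[zone.zone_id] = {
            "area_ha": zone.area_ha,
            "log_density": math.log(effective / zone.area_ha),
        }
    for name in stack.names:
        means = zonal_mean(stack[name], zones)
        for zid, value in means.items():
            rows[zid][name] = value
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "zone_id"
    return table.sort_index()


def fit_density_model(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
) -> DensityModel:
    """Fit the random forest of log density on zonal covariate means.

    Regression defaults: ceil(p/3) features per split, unlimited depth,
    bootstrap resampling.  OOB diagnostics are computed from the out-of-bag
    predictions; a constant response yields a warning and a model that
    predicts the constant.
    """
    covariates = [c for c in table.columns if c not in ("area_ha", "log_density")]
    if len(table) < 10:
        raise GridError("need at least 10 zones to fit the density model")
    X = table[covariates].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise GridError("missing covariate values in feature table")
    y = table["log_density"].to_numpy(dtype=np.float64)

    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, math.ceil(len(covariates) / 3)),
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # oob_score emits a warning when a sample is never out of bag;
        # handled below via nan-aware aggregation.
        warnings.simplefilter("ignore", UserWarning)
        rf.fit(X, y)

    oob_pred = rf.oob_prediction_
    seen = np.isfinite(oob_pred)
    oob_mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2)) if seen.any() else float("nan")
    var = float(np.var(y))
    if var > 0:
        pseudo_r2 = 1.0 - oob_mse / var
    else:
        warnings.warn("constant response: model predicts the constant", stacklevel=2)
        pseudo_r2 = 0.0
    return DensityModel(
        regressor=rf,
        covariate_names=covariates,
        n_trees=n_trees,
        oob_mse=oob_mse,
        oob_pseudo_r2=pseudo_r2,
        seed=seed,
        response_range=(float(y.min()), float(y.max())),
    )


def predict_weight_surface(
    model: DensityModel,
    stack: CovariateStack,
    mask: Grid,
) -> WeightSurface:
    """Per-cell weights ``exp(predicted log density)``; zero where masked.

    ``mask`` is binary habitability: 1 = habitable, anything else (or nodata
    in any covariate layer) forces the weight to zero.
    """
    template = stack.template
    if not template.same_georef(mask):
        raise GridError("mask is not aligned with the covariate stack")
    missing = [n for n in model.covariate_names if n not in stack.layers]
    if missing:
        raise GridError(f"missing covariate layer(s): {', '.join(missing)}")

    valid = mask.valid_mask & (mask.values == 1)
    for name in model.covariate_names:
        valid &= stack[name].valid_mask

    weights = np.zeros(template.shape, dtype=np.float64)
    if valid.any():
        X = np.column_stack(
            [stack[name].values[valid].astype(np.float64) for name in model.covariate_names]
        )
        weights[valid] = np.exp(model.predict_log_density(X))
    grid = template.like(weights, nodata=-1.0)
    return WeightSurface(grid, habitable=valid, provenance="rf-log-density")


def redistribute(weights: WeightSurface, zones: ZoneSet, year: int) -> PopulationGrid:
    """Dasymetric redistribution of census counts over each zone's cells.

    Within each zone, ``persons_i = N_z * w_i / sum_j w_j``.  A zone whose
    weights sum to zero falls back to a uniform allocation over its habitable
    cells, or over all of its cells if none are habitable, so every census
    count is always placed somewhere in its own zone.
    """
    grid = weights.weights
    labels, ids = rasterize_zones(zones, grid)
    counts = zones.counts_for(year)
    persons = np.zeros(grid.shape, dtype=np.float64)
    empty: list[str] = []
    for idx, zid in enumerate(ids):
        cells = labels == idx
        n_cells = int(cells.sum())
        if n_cells == 0:
            empty.append(zid)
            continue
        count = counts[zid]
        w = grid.values[cells]
        total_w = w.sum()
        if total_w > 0:
            persons[cells] = count * w / total_w
        else:
            hab = cells & weights.habitable
            target = hab if hab.any() else cells
            persons[target] = count / target.sum()
    if empty:
        raise GridError(f"zone(s) contain no grid cells: {', '.join(empty)}")
    return PopulationGrid(grid.like(persons, nodata=-1.0))


def reaggregate_check(
    pop: PopulationGrid,
    check_zones: ZoneSet,
    year: int,
) -> tuple[dict[str, float], float]:
    """Aggregate the grid back to (possibly different) zones and correlate.

    Returns per-zone aggregated populations and the Pearson correlation with
    the zones' reference counts — the standard hold-out validation for a
    disaggregated surface.
    """
    if len(check_zones) < 3:
        raise GridError("need at least 3 zones for a correlation check")
    labels, ids = rasterize_zones(check_zones, pop.persons)
    counts = check_zones.counts_for(year)
    inside = labels >= 0
    sums_arr = np.bincount(
        labels[inside], weights=pop.persons.values[inside], minlength=len(ids)
    )
    sums = {zid: float(sums_arr[i]) for i, zid in enumerate(ids)}
    ref = np.array([counts[zid] for zid in ids], dtype=np.float64)
    est = sums_arr.astype(np.float64)
    if np.std(ref) == 0 or np.std(est) == 0:
        raise GridError("correlation undefined for constant totals")
    r = float(np.corrcoef(est, ref)[0, 1])
    return sums, r
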