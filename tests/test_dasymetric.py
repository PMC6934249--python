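"""Random-forest density model, weight surface, and count redistribution."""

import math

import numpy as np
import pandas as pd
import pytest

from magpie.dasymetric import (
    PopulationGrid,
    WeightSurface,
    build_feature_table,
    fit_density_model,
    predict_weight_surface,
    reaggregate_check,
    redistribute,
)
from magpie.grid import CovariateStack, Grid, GridError, Zone, ZoneSet
from magpie.pipeline import disaggregate
from magpie.synth import generate_landscape, random_scene_spec
from shapely.geometry import box


def make_table(n_zones, seed=0, response="monotone"):
    """Zone-level design table with a controllable covariate-response link."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n_zones)
    extra = rng.uniform(0, 1, n_zones)
    if response == "monotone":
        y = 3.0 * x - 1.0  # exact monotone function of one covariate
    elif response == "noise":
        y = rng.normal(0, 1, n_zones)
    else:
        y = np.full(n_zones, float(response))
    return pd.DataFrame(
        {"area_ha": np.full(n_zones, 100.0), "log_density": y, "x": x, "extra": extra},
        index=pd.Index([f"z{i:03d}" for i in range(n_zones)], name="zone_id"),
    )


class TestFeatureTable:
    def test_log_density_definition(self, zone_factory, grid_factory):
        zones = zone_factory([("z", (0, 0, 1000, 1000), 1000)])  # 100 ha, 1000 people
        stack = CovariateStack({"c": grid_factory(np.ones((10, 10)))})
        table = build_feature_table(zones, stack, 2011)
        assert table.loc["z", "log_density"] == pytest.approx(math.log(10.0))

    def test_zero_count_uses_pseudocount(self, zone_factory, grid_factory):
        zones = zone_factory([("z", (0, 0, 1000, 1000), 0)])
        stack = CovariateStack({"c": grid_factory(np.ones((10, 10)))})
        table = build_feature_table(zones, stack, 2011, zero_count_epsilon=0.5)
        assert table.loc["z", "log_density"] == pytest.approx(math.log(0.005))

    def test_covariate_columns_equal_zonal_means(self):
        from magpie.grid import zonal_mean

        scene = generate_landscape(random_scene_spec(0, shape=(40, 40), n_districts=5, n_settlements=3))
        table = build_feature_table(scene.zones, scene.stack, scene.year)
        for name in scene.stack.names:
            expected = zonal_mean(scene.stack[name], scene.zones)
            for zid, value in expected.items():
                assert table.loc[zid, name] == pytest.approx(value)

    def test_zero_area_zone_raises(self, grid_factory):
        from shapely.geometry import Polygon

        zones = ZoneSet([Zone("z", Polygon(), {2011: 5})], crs="t")
        stack = CovariateStack({"c": grid_factory(np.ones((4, 4)))})
        with pytest.raises(GridError):
            build_feature_table(zones, stack, 2011, zero_count_epsilon=0.5)


class TestFitDensityModel:
    def test_monotone_response_has_high_oob_r2(self):
        model = fit_density_model(make_table(200, seed=1), n_trees=500, seed=1)
        assert model.oob_pseudo_r2 > 0.9

    def test_pure_noise_response_has_low_oob_r2(self):
        model = fit_density_model(make_table(200, seed=2, response="noise"), n_trees=500, seed=2)
        assert model.oob_pseudo_r2 <= 0.1

    def test_constant_response_warns_and_predicts_constant(self):
        table = make_table(20, seed=3, response=1.5)
        with pytest.warns(UserWarning, match="constant"):
            model = fit_density_model(table, n_trees=50, seed=3)
        pred = model.predict_log_density(table[["x", "extra"]].to_numpy())
        np.testing.assert_allclose(pred, 1.5)

    def test_deterministic_for_fixed_seed(self):
        table = make_table(50, seed=4)
        m1 = fit_density_model(table, n_trees=100, seed=9)
        m2 = fit_density_model(table, n_trees=100, seed=9)
        X = table[["x", "extra"]].to_numpy()
        np.testing.assert_array_equal(m1.predict_log_density(X), m2.predict_log_density(X))
        assert m1.oob_mse == m2.oob_mse

    def test_too_few_rows_raise(self):
        with pytest.raises(GridError, match="10"):
            fit_density_model(make_table(5))

    def test_predictions_stay_within_training_range(self):
        table = make_table(100, seed=5)
        model = fit_density_model(table, n_trees=100, seed=5)
        X = np.column_stack([np.linspace(-5, 5, 50), np.linspace(-5, 5, 50)])
        pred = model.predict_log_density(X)
        lo, hi = model.response_range
        assert pred.min() >= lo - 1e-9 and pred.max() <= hi + 1e-9


class TestWeightSurface:
    def test_masked_cells_have_zero_weight(self, grid_factory):
        table = make_table(20, seed=6)
        model = fit_density_model(table, n_trees=50, seed=6)
        stack = CovariateStack(
            {"x": grid_factory(np.full((3, 3), 0.5)), "extra": grid_factory(np.full((3, 3), 0.5))}
        )
        mask = grid_factory([[1, 1, 0], [1, 0, 1], [1, 1, 1]])
        ws = predict_weight_surface(model, stack, mask)
        assert ws.weights.values[0, 2] == 0.0 and ws.weights.values[1, 1] == 0.0
        assert (ws.weights.values[mask.values == 1] > 0).all()

    def test_constant_model_gives_exp_constant(self, grid_factory):
        table = make_table(20, seed=7, response=2.0)
        with pytest.warns(UserWarning):
            model = fit_density_model(table, n_trees=50, seed=7)
        stack = CovariateStack(
            {"x": grid_factory(np.zeros((2, 2))), "extra": grid_factory(np.zeros((2, 2)))}
        )
        ws = predict_weight_surface(model, stack, grid_factory(np.ones((2, 2))))
        np.testing.assert_allclose(ws.weights.values, math.exp(2.0))

    def test_missing_layer_named_in_error(self, grid_factory):
        model = fit_density_model(make_table(20, seed=8), n_trees=20, seed=8)
        stack = CovariateStack({"x": grid_factory(np.zeros((2, 2)))})
        with pytest.raises(GridError, match="extra"):
            predict_weight_surface(model, stack, grid_factory(np.ones((2, 2))))


class TestRedistribute:
    def make_weights(self, values, habitable=None, cell=100.0):
        values = np.asarray(values, dtype=float)
        grid = Grid(values, 0.0, values.shape[0] * cell, cell, crs="t", nodata=-1.0)
        hab = np.ones(values.shape, bool) if habitable is None else np.asarray(habitable, bool)
        return WeightSurface(grid, habitable=hab)

    def test_uniform_weights_split_evenly(self, zone_factory):
        ws = self.make_weights(np.ones((2, 2)))
        zones = zone_factory([("z", (0, 0, 200, 200), 100)])
        pop = redistribute(ws, zones, 2011)
        np.testing.assert_allclose(pop.persons.values, 25.0)

    def test_proportional_weights(self, zone_factory):
        ws = self.make_weights([[1.0, 3.0]])
        zones = zone_factory([("z", (0, 0, 200, 100), 100)])
        pop = redistribute(ws, zones, 2011)
        np.testing.assert_allclose(pop.persons.values, [[25.0, 75.0]])

    def test_zero_weight_zone_falls_back_to_uniform_habitable(self, zone_factory):
        hab = np.array([[True, False], [True, True]])
        ws = self.make_weights(np.zeros((2, 2)), habitable=hab)
        zones = zone_factory([("z", (0, 0, 200, 200), 90)])
        pop = redistribute(ws, zones, 2011)
        np.testing.assert_allclose(pop.persons.values, [[30.0, 0.0], [30.0, 30.0]])
        assert pop.total == pytest.approx(90.0)

    def test_conservation_over_random_zones_and_weights(self, zone_factory):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 5, (20, 20))
        vals[:, 10:12] = 0.0  # a stripe of all-zero weights
        ws = self.make_weights(vals)
        rects, counts = [], {}
        for i in range(20):  # 20 zones: 4 x 5 tiling of the 2 km square
            r, c = divmod(i, 5)
            zid = f"z{i:02d}"
            count = int(rng.integers(0, 5000))
            rects.append((zid, (c * 400, r * 500, (c + 1) * 400, (r + 1) * 500), count))
            counts[zid] = count
        zones = zone_factory(rects)
        pop = redistribute(ws, zones, 2011)
        from magpie.grid import rasterize_zones

        labels, ids = rasterize_zones(zones, ws.weights)
        for idx, zid in enumerate(ids):
            total = pop.persons.values[labels == idx].sum()
            assert total == pytest.approx(counts[zid], rel=1e-6)

    def test_zone_with_no_cells_raises(self, zone_factory):
        ws = self.make_weights(np.ones((2, 2)))
        zones = zone_factory([("ok", (0, 0, 200, 200), 10), ("empty", (900, 900, 950, 950), 5)])
        with pytest.raises(GridError, match="empty"):
            redistribute(ws, zones, 2011)


class TestReaggregateCheck:
    def test_identity_zones_give_perfect_correlation(self):
        scene = generate_landscape(random_scene_spec(12, shape=(50, 50), n_districts=15, n_settlements=5))
        res = disaggregate(scene.zones, scene.stack, scene.mask, scene.year, n_trees=100, seed=12)
        sums, r = reaggregate_check(res.population, scene.zones, scene.year)
        counts = scene.zones.counts_for(scene.year)
        assert r == pytest.approx(1.0)
        for zid, total in sums.items():
            assert total == pytest.approx(counts[zid], rel=1e-6)

    def test_shuffled_counts_kill_correlation(self):
        scene = generate_landscape(random_scene_spec(13, n_districts=200, n_settlements=12))
        res = disaggregate(scene.zones, scene.stack, scene.mask, scene.year, n_trees=100, seed=13)
        rng = np.random.default_rng(13)
        shuffled = rng.permutation([z.counts[scene.year] for z in scene.zones])
        shuffled_zones = ZoneSet(
            [
                Zone(z.zone_id, z.geometry, {scene.year: int(c)})
                for z, c in zip(scene.zones, shuffled)
            ],
            crs=scene.zones.crs,
        )
        _, r = reaggregate_check(res.population, shuffled_zones, scene.year)
        assert abs(r) < 0.3

    def test_too_few_zones_raise(self, zone_factory):
        grid = Grid(np.ones((2, 2)), 0.0, 200.0, 100.0, crs="t", nodata=-1.0)
        pop = PopulationGrid(grid)
        zones = zone_factory([("a", (0, 0, 100, 200), 2), ("b", (100, 0, 200, 200), 2)])
        with pytest.raises(GridError, match="3"):
            reaggregate_check(pop, zones, 2011)


class TestPipelineDeterminism:
    def test_identical_inputs_and_seed_give_bit_identical_outputs(self):
        scene = generate_landscape(random_scene_spec(21, shape=(40, 40), n_districts=12, n_settlements=4))
        r1 = disaggregate(scene.zones, scene.stack, scene.mask, scene.year, n_trees=80, seed=5)
        r2 = disaggregate(scene.zones, scene.stack, scene.mask, scene.year, n_trees=80, seed=5)
        np.testing.assert_array_equal(r1.weights.weights.values, r2.weights.weights.values)
        np.testing.assert_array_equal(r1.population.persons.values, r2.population.persons.values)
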