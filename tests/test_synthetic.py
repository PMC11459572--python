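"""Synthetic-data generator: determinism, structure, and generative consistency."""

import numpy as np
import pytest

from fertimap.grids import GridSpec
from fertimap.kriging import MaternParams, matern_correlation
from fertimap.rates import weighted_rates
from fertimap.seeding import substream_seed
from fertimap.synthetic import (
    COVARIATE_NAMES,
    SimulationConfig,
    clusters_frame,
    seeded_city_points,
    simulate_admin_units,
    simulate_birth_histories,
    simulate_cluster_proportions,
    simulate_clusters,
    simulate_covariate_rasters,
    simulate_matern_field,
)


class TestCovariateRasters:
    def test_grid_arithmetic_and_no_nodata(self):
        cfg = SimulationConfig(region_extent=(0, 0, 100, 100), cell_km=1.0, seed=2)
        stack = simulate_covariate_rasters(cfg)
        assert set(stack.names) == set(COVARIATE_NAMES)
        for name in stack.names:
            assert stack[name].values.shape == (100, 100)
            assert np.isfinite(stack[name].values).all()

    def test_city_pixel_distance_zero(self):
        cfg = SimulationConfig(seed=5)
        stack = simulate_covariate_rasters(cfg)
        cities = seeded_city_points(cfg)
        r, c = cfg.grid.index_of(cities[:, 0], cities[:, 1])
        assert (stack["travel_time_city"].values[r, c] == 0.0).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=9)
        a = simulate_covariate_rasters(cfg)
        b = simulate_covariate_rasters(cfg)
        for name in a.names:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_population_density_positive(self):
        stack = simulate_covariate_rasters(SimulationConfig(seed=3))
        assert (stack["pop_density"].values > 0).all()

    def test_proportion_surface_in_unit_interval(self):
        stack = simulate_covariate_rasters(SimulationConfig(seed=3))
        v = stack["prop_muslim"].values
        assert (v > 0).all() and (v < 1).all()

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            SimulationConfig(region_extent=(0, 0, 0, 100))


class TestMaternField:
    def test_zero_variance_gives_zero_field(self):
        grid = GridSpec(0, 0, 1.0, 20, 20)
        f = simulate_matern_field(grid, MaternParams(0.0, 10.0), seed=1)
        assert (f.values == 0).all()

    def test_determinism(self):
        grid = GridSpec(0, 0, 1.0, 30, 30)
        p = MaternParams(0.5, 12.0)
        a = simulate_matern_field(grid, p, seed=4)
        b = simulate_matern_field(grid, p, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_monte_carlo_variance(self):
        """Empirical pixel variance over 200 draws within 15% of sigma2."""
        grid = GridSpec(0, 0, 1.0, 25, 25)
        p = MaternParams(sigma2=1.0, range_km=10.0)
        draws = np.array([
            simulate_matern_field(grid, p, seed=s).values[12, 12]
            for s in range(200)
        ])
        assert abs(draws.var() - p.sigma2) < 0.15 * p.sigma2

    def test_monte_carlo_correlation_at_range(self):
        """Empirical correlation at d = range matches the Matérn value (tol 0.1)."""
        grid = GridSpec(0, 0, 1.0, 25, 25)
        p = MaternParams(sigma2=1.0, range_km=10.0)
        a, b = [], []
        for s in range(200):
            v = simulate_matern_field(grid, p, seed=1000 + s).values
            a.append(v[12, 7])
            b.append(v[12, 17])  # 10 km apart
        emp = np.corrcoef(a, b)[0, 1]
        expected = matern_correlation(p.range_km, p.range_km, p.nu)
        assert abs(emp - expected) < 0.1


class TestClusters:
    def test_all_rural_when_fraction_zero(self):
        cl = simulate_clusters(SimulationConfig(urban_fraction=0.0, seed=1))
        assert not any(c.urban for c in cl)

    def test_urban_count_rounding_contract(self):
        cl = simulate_clusters(
            SimulationConfig(n_clusters=250, urban_fraction=0.2, seed=1)
        )
        assert sum(c.urban for c in cl) == 50

    def test_weights_normalized_to_mean_one(self):
        cl = simulate_clusters(SimulationConfig(seed=2))
        assert np.mean([c.weight for c in cl]) == pytest.approx(1.0, abs=1e-12)

    def test_geometry_inside_extent(self):
        cfg = SimulationConfig(region_extent=(10, 20, 70, 90), seed=3)
        for c in simulate_clusters(cfg):
            assert 10 <= c.x_km <= 70 and 20 <= c.y_km <= 90

    def test_too_many_clusters_rejected(self):
        cfg = SimulationConfig(region_extent=(0, 0, 5, 5), n_clusters=26, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_clusters(cfg)


class TestBirthHistories:
    def test_birth_months_inside_window(self, small_config, small_world):
        stack, field, clusters = small_world
        women = simulate_birth_histories(clusters, stack, field, small_config)
        doi = small_config.doi_cmc
        for w in women:
            for cd in w.child_dobs_cmc:
                assert doi - 36 < cd <= doi

    def test_determinism(self, small_config, small_world):
        stack, field, clusters = small_world
        a = simulate_birth_histories(clusters, stack, field, small_config)
        b = simulate_birth_histories(clusters, stack, field, small_config)
        assert [w.child_dobs_cmc for w in a] == [w.child_dobs_cmc for w in b]

    def test_floor_region_produces_no_births(self):
        """Intercept far below zero floors the rate near zero births."""
        cfg = SimulationConfig(
            region_extent=(0, 0, 30, 30), n_clusters=20, women_per_cluster=10,
            true_intercept=-50.0, true_beta=(0.0,) * 5,
            matern=MaternParams(1e-12, 30.0), seed=6, tfr_floor=0.0,
        )
        stack = simulate_covariate_rasters(cfg)
        field = simulate_matern_field(cfg.grid, cfg.matern, 1)
        clusters = simulate_clusters(cfg)
        women = simulate_birth_histories(clusters, stack, field, cfg)
        assert sum(len(w.child_dobs_cmc) for w in women) == 0

    def test_round_trip_recovers_baseline_tfr(self):
        """With no spatial field and no effects the pooled direct TFR is
        within 5% of the generating baseline."""
        cfg = SimulationConfig(
            n_clusters=200, women_per_cluster=25,
            true_beta=(0.0,) * 5, matern=MaternParams(1e-12, 30.0), seed=21,
        )
        assert cfg.true_intercept == pytest.approx(cfg.tfr_base)
        stack = simulate_covariate_rasters(cfg)
        field = simulate_matern_field(cfg.grid, cfg.matern, 1)
        clusters = simulate_clusters(cfg)
        women = simulate_birth_histories(clusters, stack, field, cfg)
        pooled = weighted_rates(women)
        assert abs(pooled.tfr - cfg.tfr_base) / cfg.tfr_base < 0.05

    def test_missing_layer_rejected(self, small_config, small_world):
        stack, field, clusters = small_world
        partial = type(stack)(stack.grid,
                              {n: stack[n] for n in list(stack.names)[:2]})
        with pytest.raises(KeyError, match="missing"):
            simulate_birth_histories(clusters, partial, field, small_config)


class TestClusterProportions:
    def test_proportions_valid_and_deterministic(self, small_config, small_world):
        stack, _, clusters = small_world
        a = simulate_cluster_proportions(clusters, stack, small_config)
        b = simulate_cluster_proportions(clusters, stack, small_config)
        assert a.equals(b)
        assert a["proportion"].between(0, 1).all()


class TestAdminUnits:
    def test_single_region_covers_extent(self):
        grid = GridSpec(0, 0, 1.0, 40, 40)
        admin = simulate_admin_units(grid, 1, 2, seed=1)
        region = admin.at_level("region")[0]
        assert region.polygon.bounds == (0.0, 0.0, 40.0, 40.0)

    def test_zones_partition_regions(self):
        grid = GridSpec(0, 0, 1.0, 50, 50)
        admin = simulate_admin_units(grid, 3, 2, seed=2)
        for region in admin.at_level("region"):
            zones = [z for z in admin.at_level("zone")
                     if z.parent_id == region.unit_id]
            total = sum(z.polygon.area for z in zones)
            assert total == pytest.approx(region.polygon.area, rel=1e-9)

    def test_districts_nest_in_their_region(self):
        grid = GridSpec(0, 0, 1.0, 50, 50)
        admin = simulate_admin_units(grid, 2, 2, seed=3, n_districts_per_zone=2)
        lookup = admin.by_id()
        for d in admin.at_level("district"):
            zone = lookup[d.parent_id]
            region = lookup[zone.parent_id]
            assert region.polygon.contains(d.polygon.buffer(-1e-9))

    def test_partition_finer_than_grid_rejected(self):
        grid = GridSpec(0, 0, 1.0, 4, 4)
        with pytest.raises(ValueError, match="split"):
            simulate_admin_units(grid, 5, 1, seed=1)

    def test_every_pixel_assigned_once_per_level(self):
        grid = GridSpec(0, 0, 1.0, 30, 30)
        admin = simulate_admin_units(grid, 2, 3, seed=4)
        pts = grid.center_points()
        for level in ("region", "zone", "district"):
            ids = admin.assign_points(level, pts[:, 0], pts[:, 1])
            assert (ids != "").all()


def test_substreams_are_stable():
    assert substream_seed(7, "clusters") == substream_seed(7, "clusters")
    assert substream_seed(7, "clusters") != substream_seed(7, "cities")
    assert 0 <= substream_seed(123456, "x") < 2 ** 31
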