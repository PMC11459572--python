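"""Pixel prediction and small-area aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from fertimap.admin import AdminPolygons, AdminUnit
from fertimap.covariates import Standardization
from fertimap.geostat import ModelSpec, fit
from fertimap.grids import CovariateStack, GridSpec, RasterLayer
from fertimap.kriging import matern_correlation
from fertimap.prediction import (
    PredictionSurface,
    aggregate,
    predict_pixels,
    range_report,
)
from shapely.geometry import box


def _intercept_fit(rng, n=12, sigma2=0.8, rg=8.0, nug=0.3, sb=10.0, extent=20.0):
    loc = rng.uniform(0, extent, (n, 2))
    y = 4 + rng.standard_normal(n)
    design = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n)],
                                         name="cluster_id"))
    spec = ModelSpec(linear_terms=[], spatial=True, prior_sd_beta=sb,
                     sigma2_grid=[sigma2], range_grid=[rg], nugget_grid=[nug])
    return fit(spec, y, design, loc, check_collinearity=False), y, loc


class TestPredictPixels:
    def test_dense_conditional_oracle(self, rng):
        """Mean/sd match the brute-force joint-Gaussian conditional
        (12 clusters, 100 pixels, single node) to 1e-6."""
        sigma2, rg, nug, sb = 0.8, 8.0, 0.3, 10.0
        f, y, loc = _intercept_fit(rng, sigma2=sigma2, rg=rg, nug=nug, sb=sb)
        grid = GridSpec(0, 0, 2.0, 10, 10)
        surf = predict_pixels(f, CovariateStack(grid, {}),
                              Standardization({}, {}), floor_at_zero=False)
        pix = grid.center_points()
        n = len(y)
        V = sb ** 2 + sigma2 * matern_correlation(cdist(loc, loc), rg, 1.0) \
            + nug * np.eye(n)
        C = sb ** 2 + sigma2 * matern_correlation(cdist(pix, loc), rg, 1.0)
        Vi = np.linalg.inv(V)
        m_or = C @ Vi @ y
        v_or = (sb ** 2 + sigma2) - np.einsum("ij,jk,ik->i", C, Vi, C)
        np.testing.assert_allclose(surf.mean.values.ravel(), m_or, atol=1e-6)
        np.testing.assert_allclose(surf.sd.values.ravel(), np.sqrt(v_or),
                                   atol=1e-6)

    def test_far_field_reverts_to_intercept(self, rng):
        f, y, loc = _intercept_fit(rng, rg=3.0)
        far = GridSpec(400, 400, 1.0, 1, 1)
        surf = predict_pixels(f, CovariateStack(far, {}),
                              Standardization({}, {}), floor_at_zero=False)
        s = f.summary().iloc[0]
        assert abs(surf.mean.values[0, 0] - s["mean"]) < 3 * s["sd"]

    def test_sd_minimized_at_data_and_grows_with_distance(self, rng):
        """Clusters clumped in a corner: posterior sd grows along a ray."""
        loc = np.column_stack([rng.uniform(0, 3, 12), rng.uniform(0, 3, 12)])
        y = 4 + rng.standard_normal(12)
        design = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(12)],
                                             name="cluster_id"))
        spec = ModelSpec(linear_terms=[], spatial=True, sigma2_grid=[0.8],
                         range_grid=[6.0], nugget_grid=[0.1])
        f = fit(spec, y, design, loc, check_collinearity=False)
        grid = GridSpec(0, 0, 2.0, 1, 15)  # a west-east ray of pixels
        surf = predict_pixels(f, CovariateStack(grid, {}),
                              Standardization({}, {}), floor_at_zero=False)
        sds = surf.sd.values[0]
        assert (np.diff(sds[2:]) > -1e-9).all()
        assert sds[0] < sds[-1]

    def test_interval_brackets_mean_and_negative_rates_floored(self, rng):
        f, y, loc = _intercept_fit(rng)
        grid = GridSpec(0, 0, 2.0, 10, 10)
        surf = predict_pixels(f, CovariateStack(grid, {}), Standardization({}, {}))
        assert (surf.lower95.values <= surf.mean.values + 1e-9).all()
        assert (surf.mean.values <= surf.upper95.values + 1e-9).all()
        assert (surf.mean.values >= 0).all()

    def test_missing_covariate_layer_rejected(self, rng):
        n = 12
        loc = rng.uniform(0, 20, (n, 2))
        design = pd.DataFrame({"a": rng.standard_normal(n)})
        spec = ModelSpec(linear_terms=["a"], spatial=True,
                         sigma2_grid=[0.5], range_grid=[8.0], nugget_grid=[0.3])
        f = fit(spec, 4 + rng.standard_normal(n), design, loc)
        grid = GridSpec(0, 0, 2.0, 5, 5)
        with pytest.raises(KeyError, match="'a'"):
            predict_pixels(f, CovariateStack(grid, {}),
                           Standardization({"a": 0.0}, {"a": 1.0}))


def _toy_surface_and_admin():
    """2x2 pixel world split into two districts in one zone/region."""
    grid = GridSpec(0, 0, 1.0, 1, 2)
    mean = RasterLayer(grid, np.array([[4.0, 6.0]]), "mean")
    sd = RasterLayer(grid, np.zeros((1, 2)), "sd")
    lo = RasterLayer(grid, np.array([[3.0, 5.0]]), "lo")
    hi = RasterLayer(grid, np.array([[5.0, 7.0]]), "hi")
    surf = PredictionSurface(grid, mean, sd, lo, hi)
    units = [
        AdminUnit("national", "national", None, box(0, 0, 2, 1)),
        AdminUnit("R0", "region", "national", box(0, 0, 2, 1)),
        AdminUnit("R0Z0", "zone", "R0", box(0, 0, 2, 1)),
        AdminUnit("D0", "district", "R0Z0", box(0, 0, 1, 1)),
        AdminUnit("D1", "district", "R0Z0", box(1, 0, 2, 1)),
    ]
    pop = RasterLayer(grid, np.array([[1.0, 3.0]]), "pop")
    return surf, AdminPolygons(units), pop


class TestAggregate:
    def test_constant_surface_constant_everywhere(self):
        surf, admin, pop = _toy_surface_and_admin()
        c = 3.14
        for layer in (surf.mean, surf.lower95, surf.upper95):
            layer.values[:] = c
        out = aggregate(surf, admin, pop)
        np.testing.assert_allclose(out["estimate"], c)

    def test_population_weighted_parent_mean(self):
        surf, admin, pop = _toy_surface_and_admin()
        out = aggregate(surf, admin, pop).set_index("unit_id")
        assert out.loc["D0", "estimate"] == pytest.approx(4.0)
        assert out.loc["D1", "estimate"] == pytest.approx(6.0)
        # parent = (4*1 + 6*3) / 4 = 5.5
        assert out.loc["R0Z0", "estimate"] == pytest.approx(5.5)

    def test_national_consistent_with_regions(self, small_config, small_world):
        from fertimap.synthetic import simulate_admin_units

        stack, _, _ = small_world
        grid = stack.grid
        rng = np.random.default_rng(2)
        vals = rng.uniform(2, 6, grid.shape)
        surf = PredictionSurface(
            grid,
            RasterLayer(grid, vals, "m"),
            RasterLayer(grid, np.zeros(grid.shape), "s"),
            RasterLayer(grid, vals - 1, "l"),
            RasterLayer(grid, vals + 1, "u"),
        )
        admin = simulate_admin_units(grid, 3, 2, seed=5)
        pop = stack["pop_density"]
        out = aggregate(surf, admin, pop)
        regions = out[out.level == "region"]
        national = out[out.level == "national"]["estimate"].iloc[0]
        wmean = np.average(regions["estimate"], weights=regions["population"])
        assert national == pytest.approx(wmean, abs=1e-9)

    def test_unit_estimates_are_convex_combinations(self, small_world):
        from fertimap.synthetic import simulate_admin_units

        stack, _, _ = small_world
        grid = stack.grid
        vals = np.random.default_rng(3).uniform(1, 9, grid.shape)
        surf = PredictionSurface(
            grid, RasterLayer(grid, vals, "m"),
            RasterLayer(grid, np.zeros(grid.shape), "s"),
            RasterLayer(grid, vals, "l"), RasterLayer(grid, vals, "u"),
        )
        admin = simulate_admin_units(grid, 2, 2, seed=6)
        out = aggregate(surf, admin, stack["pop_density"])
        assert (out["estimate"] >= vals.min() - 1e-12).all()
        assert (out["estimate"] <= vals.max() + 1e-12).all()

    def test_zero_population_unit_flagged_unweighted(self):
        surf, admin, pop = _toy_surface_and_admin()
        pop.values[:] = 0.0
        out = aggregate(surf, admin, pop).set_index("unit_id")
        assert out["zero_population"].all()
        assert out.loc["R0Z0", "estimate"] == pytest.approx(5.0)  # plain mean

    def test_nonconforming_population_rejected(self):
        surf, admin, _ = _toy_surface_and_admin()
        bad_pop = RasterLayer(GridSpec(0, 0, 1.0, 2, 2), np.ones((2, 2)), "p")
        with pytest.raises(ValueError, match="conform"):
            aggregate(surf, admin, bad_pop)

    def test_polygon_outside_grid_rejected(self):
        surf, admin, pop = _toy_surface_and_admin()
        admin.units.append(
            AdminUnit("far", "district", "R0Z0", box(50, 50, 60, 60))
        )
        with pytest.raises(ValueError, match="far"):
            aggregate(surf, admin, pop)


class TestRangeReport:
    def test_single_unit_min_equals_max(self):
        surf, admin, pop = _toy_surface_and_admin()
        out = aggregate(surf, admin, pop)
        rep = range_report(out).set_index("level")
        assert rep.loc["national", "min"] == rep.loc["national", "max"]

    def test_ranges_nest_across_levels(self):
        """Averaging contracts ranges: pixel ⊇ district ⊇ region."""
        surf, admin, pop = _toy_surface_and_admin()
        out = aggregate(surf, admin, pop)
        rep = range_report(out, surf).set_index("level")
        for fine, coarse in (("pixel", "district"), ("district", "region")):
            assert rep.loc[fine, "min"] <= rep.loc[coarse, "min"] + 1e-12
            assert rep.loc[fine, "max"] >= rep.loc[coarse, "max"] - 1e-12

    def test_deterministic_regeneration(self):
        surf, admin, pop = _toy_surface_and_admin()
        a = range_report(aggregate(surf, admin, pop), surf)
        b = range_report(aggregate(surf, admin, pop), surf)
        pd.testing.assert_frame_equal(a, b)
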