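"""Gaussian GAM with Matérn random effect: exactness, conjugacy, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal, norm

from fertimap.geostat import (
    FitNode,
    ModelSpec,
    compare_models,
    fit,
    gaussian_mixture_quantile,
    marginal_loglik,
    spline_basis,
)
from fertimap.kriging import MaternParams, matern_correlation


def _sim_gaussian(seed, n, sigma2, range_km, nugget, beta, intercept=4.5):
    """Direct draw from the observation model (no birth-history layer)."""
    rng = np.random.default_rng(seed)
    loc = rng.uniform(0, 100, (n, 2))
    X = rng.standard_normal((n, len(beta)))
    X = (X - X.mean(0)) / X.std(0)
    u = np.zeros(n)
    if sigma2 > 0:
        R = matern_correlation(cdist(loc, loc), range_km, 1.0)
        u = np.linalg.cholesky(sigma2 * R + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
    y = intercept + X @ beta + u + math.sqrt(nugget) * rng.standard_normal(n)
    cols = [f"x{i}" for i in range(len(beta))]
    return pd.DataFrame(X, columns=cols), y, loc


class TestSplineBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(-2, 2, 60)
        B, P, t = spline_basis(x, 8)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_penalty_annihilates_linear_coefficients(self):
        x = np.linspace(0, 1, 30)
        B, P, _ = spline_basis(x, 7)
        coefs = 2.0 + 3.0 * np.arange(7)
        assert coefs @ P @ coefs == pytest.approx(0.0, abs=1e-10)

    def test_deterministic_evaluation(self, rng):
        x = rng.uniform(0, 1, 40)
        B1, _, _ = spline_basis(x, 6)
        B2, _, _ = spline_basis(x, 6)
        np.testing.assert_array_equal(B1, B2)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([0.0, 1.0, 1.0, 0.0, 1.0]), 4)

    def test_small_basis_rejected(self):
        with pytest.raises(ValueError, match="K"):
            spline_basis(np.linspace(0, 1, 10), 3)


class TestMarginalLoglik:
    def test_single_standard_normal_observation(self):
        """n=1, total variance 1, y=0: the standard normal log-density."""
        node = FitNode(nugget=1.0)
        got = marginal_loglik(node, np.array([0.0]))
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_multivariate_normal_oracle(self, rng):
        """Evidence identity vs scipy's dense MVN log-density, 1e-8."""
        n = 10
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        loc = rng.uniform(0, 50, (n, 2))
        y = rng.standard_normal(n)
        sb = 2.5
        node = FitNode(nugget=0.3, matern=MaternParams(0.8, 12.0, 1.0))
        V = (sb ** 2) * X @ X.T \
            + 0.8 * matern_correlation(cdist(loc, loc), 12.0, 1.0) \
            + 0.3 * np.eye(n)
        oracle = multivariate_normal(mean=np.zeros(n), cov=V).logpdf(y)
        got = marginal_loglik(node, y, X, locations=loc, prior_sd_beta=sb)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_true_model_beats_mismatched_on_average(self):
        """Average per-observation evidence favors the generating hypers."""
        wins = 0
        for seed in range(20):
            X, y, loc = _sim_gaussian(seed, 40, 0.8, 20.0, 0.2,
                                      np.array([0.4]))
            Xd = np.column_stack([np.ones(40), X.to_numpy()])
            good = FitNode(nugget=0.2, matern=MaternParams(0.8, 20.0, 1.0))
            bad = FitNode(nugget=2.5, matern=MaternParams(0.01, 2.0, 1.0))
            lg = marginal_loglik(good, y, Xd, locations=loc)
            lb = marginal_loglik(bad, y, Xd, locations=loc)
            wins += lg > lb
        assert wins >= 15


class TestFit:
    def test_flat_prior_matches_least_squares(self, rng):
        n = 80
        Xd = rng.standard_normal((n, 3))
        beta = np.array([4.5, 0.4, -0.2, 0.1])
        y = beta[0] + Xd @ beta[1:] + 0.3 * rng.standard_normal(n)
        design = pd.DataFrame(Xd, columns=list("abc"))
        spec = ModelSpec(linear_terms=list("abc"), spatial=False,
                         prior_sd_beta=1e4, nugget_grid=[0.09])
        f = fit(spec, y, design)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), Xd]), y, rcond=None)[0]
        np.testing.assert_allclose(f.summary()["mean"].to_numpy(), ols, atol=1e-6)

    def test_posterior_exact_against_dense_conditional_oracle(self, rng):
        """Per-node posterior mean/cov equal the brute-force Gaussian
        conditional computed from the joint covariance (n <= 30)."""
        n = 25
        X, y, loc = _sim_gaussian(3, n, 0.5, 15.0, 0.2, np.array([0.3, -0.2]))
        sb, s2, rg, ng = 10.0, 0.5, 15.0, 0.2
        spec = ModelSpec(linear_terms=list(X.columns), spatial=True,
                         prior_sd_beta=sb, sigma2_grid=[s2], range_grid=[rg],
                         nugget_grid=[ng])
        f = fit(spec, y, X, loc)
        means, sds = f.fixed_effect_posteriors()
        # oracle: theta = (b0, b, u); y = A theta + eps
        A = np.column_stack([np.ones(n), X.to_numpy(), np.eye(n)])
        R = matern_correlation(cdist(loc, loc), rg, 1.0)
        S0 = np.zeros((3 + n, 3 + n))
        S0[:3, :3] = sb ** 2 * np.eye(3)
        S0[3:, 3:] = s2 * R
        V = A @ S0 @ A.T + ng * np.eye(n)
        G = S0 @ A.T @ np.linalg.inv(V)
        post_mean = G @ y
        post_cov = S0 - G @ A @ S0
        np.testing.assert_allclose(means[0], post_mean[:3], atol=1e-8)
        np.testing.assert_allclose(sds[0], np.sqrt(np.diag(post_cov)[:3]),
                                   atol=1e-8)

    def test_shrinkage_never_exceeds_least_squares_norm(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 40
            Xd = r.standard_normal((n, 3))
            y = 1.0 + Xd @ np.array([0.5, -0.3, 0.2]) + r.standard_normal(n)
            design = pd.DataFrame(Xd, columns=list("abc"))
            spec = ModelSpec(linear_terms=list("abc"), spatial=False,
                             prior_sd_beta=0.5, nugget_grid=[1.0])
            f = fit(spec, y, design)
            post = f.summary()["mean"].to_numpy()
            ols = np.linalg.lstsq(np.column_stack([np.ones(n), Xd]), y,
                                  rcond=None)[0]
            assert np.linalg.norm(post) <= np.linalg.norm(ols) + 1e-12

    def test_reproducible_summary(self):
        X, y, loc = _sim_gaussian(5, 60, 0.4, 20.0, 0.3, np.array([0.4, 0.1]))
        spec = ModelSpec(linear_terms=list(X.columns), spatial=True)
        a = fit(spec, y, X, loc).summary()
        b = fit(spec, y, X, loc).summary()
        pd.testing.assert_frame_equal(a, b)

    def test_credible_interval_ordering(self):
        X, y, loc = _sim_gaussian(6, 60, 0.4, 20.0, 0.3, np.array([0.4]))
        spec = ModelSpec(linear_terms=list(X.columns), spatial=True)
        s = fit(spec, y, X, loc).summary()
        assert (s["lower95"] <= s["mean"]).all() and (s["mean"] <= s["upper95"]).all()

    def test_smooth_term_captures_nonlinearity(self, rng):
        n = 150
        x = rng.uniform(-2, 2, n)
        y = 4.0 + np.sin(1.5 * x) + 0.2 * rng.standard_normal(n)
        design = pd.DataFrame({"x": x})
        spec = ModelSpec(linear_terms=[], smooth_terms={"x": 8}, spatial=False)
        f = fit(spec, y, design)
        # reconstruct the fitted smooth at the best node and check shape
        best = int(np.argmax(f.weights))
        from fertimap.geostat import eval_spline_basis

        grid_x = np.linspace(-1.5, 1.5, 25)
        B = eval_spline_basis(grid_x, f.smooth_knots["x"])
        m = f.post_means[best]
        smooth = B @ m[f.slices["x"]] + m[f.slices["fixed"]][0]
        target = 4.0 + np.sin(1.5 * grid_x)
        assert np.max(np.abs(smooth - target)) < 0.35

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(50)
        design = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.standard_normal(50)})
        y = x + rng.standard_normal(50)
        with pytest.raises(ValueError, match="collinearity"):
            fit(ModelSpec(linear_terms=["a", "b"], spatial=False), y, design)

    def test_spatial_needs_ten_clusters(self, rng):
        design = pd.DataFrame({"a": rng.standard_normal(8)})
        with pytest.raises(ValueError, match="10 clusters"):
            fit(ModelSpec(linear_terms=["a"], spatial=True),
                rng.standard_normal(8), design, rng.uniform(0, 10, (8, 2)))

    def test_shared_covariate_in_both_term_sets_rejected(self):
        with pytest.raises(ValueError, match="both"):
            ModelSpec(linear_terms=["a"], smooth_terms={"a": 5})


class TestMixtureQuantile:
    def test_single_component_matches_normal(self):
        q = gaussian_mixture_quantile([1.0], [2.0], [1.0], 0.975)
        assert q == pytest.approx(norm.ppf(0.975, 1.0, 2.0), abs=1e-5)

    def test_two_component_median_lies_on_half_mass_plateau(self):
        # between well-separated modes the CDF is flat at 1/2; any point
        # there is a valid median
        q = gaussian_mixture_quantile([-1.0, 1.0], [0.1, 0.1], [0.5, 0.5], 0.5)
        cdf = 0.5 * (norm.cdf(q, -1.0, 0.1) + norm.cdf(q, 1.0, 0.1))
        assert cdf == pytest.approx(0.5, abs=1e-6)
        assert -1.0 < q < 1.0


class TestCompareModels:
    def test_identical_fits_tie_at_zero(self):
        X, y, loc = _sim_gaussian(8, 50, 0.4, 20.0, 0.3, np.array([0.4]))
        spec = ModelSpec(linear_terms=list(X.columns), spatial=True)
        f1 = fit(spec, y, X, loc)
        f2 = fit(spec, y, X, loc)
        cm = compare_models(f1, f2)
        assert cm.delta_log_marginal == pytest.approx(0.0, abs=1e-9)
        assert cm.preferred == "tie"

    def test_mismatched_sample_sizes_rejected(self):
        Xa, ya, la = _sim_gaussian(9, 40, 0.4, 20.0, 0.3, np.array([0.4]))
        Xb, yb, lb = _sim_gaussian(9, 30, 0.4, 20.0, 0.3, np.array([0.4]))
        spec = ModelSpec(linear_terms=list(Xa.columns), spatial=True)
        with pytest.raises(ValueError, match="different n"):
            compare_models(fit(spec, ya, Xa, la), fit(spec, yb, Xb, lb))

    def test_strong_field_prefers_spatial(self):
        X, y, loc = _sim_gaussian(10, 150, 1.5, 25.0, 0.2, np.array([0.4, 0.2]))
        fs = fit(ModelSpec(linear_terms=list(X.columns), spatial=True), y, X, loc)
        fn = fit(ModelSpec(linear_terms=list(X.columns), spatial=False), y, X)
        assert compare_models(fs, fn).preferred == "spatial"
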