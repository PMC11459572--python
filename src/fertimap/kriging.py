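"""Bayesian kriging of a cluster-level proportion onto a prediction grid.

A Gaussian process with Matérn correlation and an iid nugget is the spatial
model everywhere in this package; this module owns the Matérn family and
the kriging interpolator used to turn sparse cluster-level proportions
(e.g. the proportion of Muslim women per survey cluster) into a smooth
covariate surface with uncertainty.

"Bayesian" here means full deterministic integration over a grid of
(partial sill, range, nugget) hyperparameter nodes: the Gaussian marginal
likelihood is evaluated exactly at every node, combined with independent
log-normal priors, and predictions are mixed over the normalized node
weights.  No MCMC is involved, so results are exactly reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from scipy.special import gammaln, kv

from .grids import GridSpec, RasterLayer

__all__ = [
    "MaternParams",
    "matern_correlation",
    "matern_covariance",
    "KrigeFit",
    "krige_fit",
    "krige_predict",
]


@dataclass(frozen=True)
class MaternParams:
    """Hyperparameters of a Matérn Gaussian field with nugget.

    sigma2
        Partial sill: marginal variance of the spatially structured part.
    range_km
        Spatial range phi, km.  With the kappa = sqrt(8 nu)/phi
        parameterization used here, the correlation at distance phi is
        about 0.13 for nu = 1, i.e. phi is the distance at which spatial
        correlation has become small (~0.1).
    nu
        Smoothness. nu = 0.5 is the exponential kernel; nu = 1 (the
        default throughout) corresponds to the SPDE alpha = 2 field in
        two dimensions.
    nugget
        iid variance tau^2 capturing measurement error and micro-scale
        variation; added to the covariance diagonal at data locations.
    """

    sigma2: float
    range_km: float
    nu: float = 1.0
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.range_km <= 0:
            raise ValueError(f"range_km must be positive, got {self.range_km}")
        if self.nu <= 0:
            raise ValueError(f"nu must be positive, got {self.nu}")
        if self.nugget < 0:
            raise ValueError(f"nugget must be >= 0, got {self.nugget}")


def matern_correlation(d, phi: float, nu: float = 1.0):
    """Matérn correlation at distance(s) ``d``.

    Uses rho(d) = 2^(1-nu)/Gamma(nu) * (kappa d)^nu * K_nu(kappa d) with
    kappa = sqrt(8 nu)/phi, so ``phi`` is an effective range: rho(phi)
    ~= 0.13 for nu = 1 and rho is ~0.1 shortly beyond it.  rho(0) = 1 and
    rho is strictly decreasing in d.
    """
    if phi <= 0:
        raise ValueError(f"range phi must be positive, got {phi}")
    if nu <= 0:
        raise ValueError(f"smoothness nu must be positive, got {nu}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    kappa = math.sqrt(8.0 * nu) / phi
    u = kappa * d
    out = np.ones_like(u)
    pos = u > 0
    if np.any(pos):
        up = u[pos]
        # log-space for numerical stability at large nu or large distances
        log_rho = (
            (1.0 - nu) * math.log(2.0)
            - gammaln(nu)
            + nu * np.log(up)
            + np.log(kv(nu, up))
        )
        out[pos] = np.exp(log_rho)
    # guard tiny overshoot from the Bessel evaluation near zero
    return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))


def matern_covariance(points_a: np.ndarray, points_b: Optional[np.ndarray],
                      params: MaternParams) -> np.ndarray:
    """Dense Matérn covariance between two point sets (nugget excluded)."""
    pa = np.atleast_2d(points_a)
    pb = pa if points_b is None else np.atleast_2d(points_b)
    d = cdist(pa, pb)
    return params.sigma2 * matern_correlation(d, params.range_km, params.nu)


def _chol_with_jitter(K: np.ndarray, base_jitter: float = 1e-10):
    """Cholesky with escalating diagonal jitter; raises naming the jitter."""
    scale = float(np.mean(np.diag(K))) or 1.0
    jitter = 0.0
    for k in range(8):
        try:
            return cho_factor(K + jitter * np.eye(K.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter = base_jitter * scale * 10.0 ** k
    raise np.linalg.LinAlgError(
        f"covariance not positive definite even after jitter {jitter:g}"
    )


def _gauss_loglik(resid: np.ndarray, K: np.ndarray) -> float:
    """log N(resid; 0, K) via Cholesky (jittered)."""
    cf, _ = _chol_with_jitter(K)
    alpha = cho_solve(cf, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = resid.size
    return float(-0.5 * (resid @ alpha + logdet + n * math.log(2.0 * math.pi)))


# --------------------------------------------------------------------------- fit


@dataclass
class KrigeFit:
    """Conditioning state of a Bayesian kriging fit.

    Holds the data, the prior mean, the hyperparameter nodes with their
    normalized posterior weights, and per-node Cholesky factors so that
    prediction does not refactorize.
    """

    points: np.ndarray          # (n, 2) data locations, km
    values: np.ndarray          # (n,) observed proportions
    mu0: float                  # prior mean
    nodes: List[MaternParams]
    weights: np.ndarray         # (n_nodes,) posterior weights, sum to 1
    log_posterior: np.ndarray   # unnormalized log weights (lik x prior)
    _factors: list              # per-node (cho_factor, alpha) for prediction

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def default_hyper_grid(values: np.ndarray, extent_scale: float,
                       n_sigma2: int = 11, n_range: int = 11,
                       n_nugget: int = 5, nu: float = 1.0) -> List[MaternParams]:
    """Log-spaced (sigma2, range, nugget) grid centred on data-driven scales.

    sigma2 spans two decades around the sample variance, range spans
    roughly [2%, 100%] of the domain scale, and the nugget spans from
    effectively zero to the sample variance.
    """
    v = float(np.var(values))
    if v <= 0:
        v = 1e-6
    sigma2s = v * np.logspace(-1.5, 0.8, n_sigma2)
    ranges = extent_scale * np.logspace(math.log10(0.02), 0.0, n_range)
    nuggets = v * np.logspace(-6, 0.0, n_nugget)
    return [
        MaternParams(s2, rg, nu, ng)
        for s2 in sigma2s for rg in ranges for ng in nuggets
    ]


def _log_normal_prior(node: MaternParams, values: np.ndarray,
                      extent_scale: float) -> float:
    """Independent log-normal priors on (sigma2, range, nugget).

    Defaults: ln sigma2 ~ N(ln var(y), 1.5^2), ln range ~ N(ln(0.25 L), 1.5^2)
    with L the domain scale, ln nugget ~ N(ln(0.1 var(y)), 2^2).  Weakly
    informative; they mostly keep posterior mass off absurd grid corners.
    """
    v = max(float(np.var(values)), 1e-8)
    lp = 0.0
    for val, mu, sd in (
        (node.sigma2, math.log(v), 1.5),
        (node.range_km, math.log(0.25 * extent_scale), 1.5),
        (max(node.nugget, 1e-12 * v), math.log(0.1 * v), 2.0),
    ):
        z = (math.log(val) - mu) / sd
        lp += -0.5 * z * z
    return lp


def krige_fit(points: np.ndarray, values: np.ndarray,
              hyper_grid: Optional[Sequence[MaternParams]] = None,
              mu0: Optional[float] = None,
              sample_weights: Optional[np.ndarray] = None) -> KrigeFit:
    """Fit the hyperparameter-grid Bayesian kriging model to proportions.

    Parameters
    ----------
    points, values
        Data locations (n, 2) in km and observed proportions in [0, 1];
        at least 5 points are required.
    hyper_grid
        Nodes to integrate over; defaults to an 11 x 11 x 5 log-spaced
        grid with nu fixed at 1.
    mu0
        Prior (and far-field) mean; defaults to the (weighted) mean of
        the observed values.
    sample_weights
        Optional weights used only for the default ``mu0``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    if points.shape[0] != values.size:
        raise ValueError("points and values must have matching length")
    if points.shape[0] < 5:
        raise ValueError(f"need at least 5 points, got {points.shape[0]}")
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("values must be proportions in [0, 1]")

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    extent_scale = float(np.linalg.norm(hi - lo)) or 1.0
    if mu0 is None:
        if sample_weights is not None:
            mu0 = float(np.average(values, weights=sample_weights))
        else:
            mu0 = float(np.mean(values))
    if hyper_grid is None:
        hyper_grid = default_hyper_grid(values, extent_scale)
    nodes = list(hyper_grid)

    resid = values - mu0
    d = cdist(points, points)
    log_post = np.empty(len(nodes))
    factors = []
    for i, node in enumerate(nodes):
        K = node.sigma2 * matern_correlation(d, node.range_km, node.nu)
        K[np.diag_indices_from(K)] += node.nugget
        cf, _ = _chol_with_jitter(K, base_jitter=1e-8)
        alpha = cho_solve(cf, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (resid @ alpha + logdet + resid.size * math.log(2 * math.pi))
        log_post[i] = ll + _log_normal_prior(node, values, extent_scale)
        factors.append((cf, alpha))

    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    return KrigeFit(points, values, mu0, nodes, w, log_post, factors)


def krige_predict(fit: KrigeFit, grid: GridSpec,
                  weight_floor: float = 1e-6,
                  chunk: int = 2048) -> Tuple[RasterLayer, RasterLayer]:
    """Posterior mean and sd surfaces of the latent proportion on ``grid``.

    Per hyper node the Gaussian-process conditional mean and variance of
    the *noise-free* field are computed at every pixel centre; the node
    results are mixed over the posterior weights (mixture variance =
    within-node + between-node).  The mixed mean is clipped to [0, 1]
    after mixing.  Nodes with negligible weight (< ``weight_floor``) are
    skipped; the remaining weights are renormalized.
    """
    pix = grid.center_points()
    lo = fit.points.min(axis=0)
    hi = fit.points.max(axis=0)
    max_range = max(n.range_km for n in fit.nodes)
    pad = 3.0 * max_range
    x0, y0, x1, y1 = grid.extent
    if x1 < lo[0] - pad or x0 > hi[0] + pad or y1 < lo[1] - pad or y0 > hi[1] + pad:
        warnings.warn(
            "prediction grid lies far outside the data bounding box; "
            "predictions revert to the prior mean", stacklevel=2
        )

    keep = np.nonzero(fit.weights >= weight_floor)[0]
    if keep.size == 0:
        keep = np.array([int(np.argmax(fit.weights))])
    w = fit.weights[keep]
    w = w / w.sum()

    n_pix = pix.shape[0]
    mix_mean = np.zeros(n_pix)
    mix_m2 = np.zeros(n_pix)  # E[mean^2 + var]
    for wi, idx in zip(w, keep):
        node = fit.nodes[idx]
        cf, alpha = fit._factors[idx]
        mean_i = np.empty(n_pix)
        var_i = np.empty(n_pix)
        for s in range(0, n_pix, chunk):
            block = pix[s:s + chunk]
            k = node.sigma2 * matern_correlation(
                cdist(block, fit.points), node.range_km, node.nu
            )
            mean_i[s:s + chunk] = fit.mu0 + k @ alpha
            Kik = cho_solve(cf, k.T)
            var_i[s:s + chunk] = np.maximum(
                node.sigma2 - np.einsum("ij,ji->i", k, Kik), 0.0
            )
        mix_mean += wi * mean_i
        mix_m2 += wi * (var_i + mean_i ** 2)

    var = np.maximum(mix_m2 - mix_mean ** 2, 0.0)
    mean = np.clip(mix_mean, 0.0, 1.0)
    shape = grid.shape
    return (
        RasterLayer(grid, mean.reshape(shape), "krige_mean"),
        RasterLayer(grid, np.sqrt(var).reshape(shape), "krige_sd"),
    )
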