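"""Seeded synthetic survey world: rasters, clusters, birth histories, admin units.

This module generates desk-scale inputs with the statistical structure the
downstream analysis assumes: smooth covariate surfaces on a ~1 km grid, a
latent Matérn Gaussian field, stratified two-stage survey clusters with
design weights, retrospective birth histories whose age-specific rates
follow the local latent fertility surface, cluster-level religious
proportions, and nested rectangular admin units.  Everything is a pure
function of the configuration and its seed; identical inputs give
byte-identical outputs.

The generative model for fertility mirrors the Gaussian additive model
fitted downstream: the local total fertility rate at location ``s`` is

    TFR(s) = intercept + sum_j beta_j * Xstd_j(s) + mu(s)

(floored at a small positive value), with ``Xstd`` the covariates
standardized over the cluster sample and ``mu`` a zero-mean Matérn field.
A woman's births over her 3-year pre-interview window are Poisson counts
per age-group segment with rate ``exposure_years * schedule[a] *
TFR(s)/TFR_base``, the standard piecewise-constant-hazard approximation,
which makes the direct ASFR estimator unbiased by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist
from shapely.geometry import box

from .admin import AdminPolygons, AdminUnit
from .grids import CovariateStack, Extent, GridSpec, RasterLayer
from .kriging import MaternParams, _chol_with_jitter, matern_correlation
from .rates import N_AGE_GROUPS, WomanRecord
from .seeding import substream_rng

__all__ = [
    "COVARIATE_NAMES",
    "ClusterRecord",
    "SimulationConfig",
    "simulate_covariate_rasters",
    "simulate_matern_field",
    "simulate_clusters",
    "simulate_birth_histories",
    "simulate_cluster_proportions",
    "simulate_admin_units",
    "clusters_frame",
    "women_frame",
]

#: Covariate layers produced by the generator, in the order `true_beta` follows.
COVARIATE_NAMES = [
    "travel_time_city",
    "dist_health_facility",
    "prop_muslim",
    "altitude",
    "pop_density",
]

#: Default age-specific fertility schedule (births per woman-year) for the
#: seven groups 15-19 ... 45-49.  Sums to 0.9, i.e. a baseline TFR of 4.5 —
#: a high-fertility sub-Saharan profile peaking at ages 20-29.
DEFAULT_ASFR_SCHEDULE = (0.10, 0.23, 0.22, 0.16, 0.11, 0.06, 0.02)

#: Default fixed effects per standardized covariate, on the TFR scale,
#: in COVARIATE_NAMES order: positive effects of remoteness from cities,
#: distance to health facilities and proportion Muslim, a mild altitude
#: effect, and a small negative population-density effect.
DEFAULT_TRUE_BETA = (0.42, 0.17, 0.37, 0.14, -0.01)


@dataclass
class ClusterRecord:
    """One survey cluster (primary sampling unit)."""

    cluster_id: str
    x_km: float
    y_km: float
    urban: bool
    year: int
    weight: float = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey world.

    ``true_intercept`` is on the TFR scale; ``true_beta`` entries apply to
    covariates standardized over the cluster sample, so they are per-SD
    effects comparable to the fitted coefficients.  ``base_asfr_schedule``
    fixes the age pattern; its sum times 5 is the baseline TFR that the
    intercept is usually set to.
    """

    region_extent: Extent = (0.0, 0.0, 100.0, 100.0)
    cell_km: float = 1.0
    n_clusters: int = 250
    urban_fraction: float = 0.2
    women_per_cluster: int = 25
    true_beta: Tuple[float, ...] = DEFAULT_TRUE_BETA
    true_intercept: float = 4.5
    matern: MaternParams = dc_field(
        default_factory=lambda: MaternParams(sigma2=0.25, range_km=30.0, nu=1.0)
    )
    base_asfr_schedule: Tuple[float, ...] = DEFAULT_ASFR_SCHEDULE
    seed: int = 0
    survey_year: int = 2019
    n_cities: int = 3
    n_health_facilities: int = 25
    smoothness_km: float = 10.0
    tfr_floor: float = 0.2

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.region_extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError(
                f"degenerate region extent {self.region_extent}: zero area"
            )
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError(f"urban_fraction must be in [0,1], got {self.urban_fraction}")
        for name in ("n_clusters", "women_per_cluster", "n_cities",
                     "n_health_facilities"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.base_asfr_schedule) != N_AGE_GROUPS:
            raise ValueError(f"base_asfr_schedule needs {N_AGE_GROUPS} entries")
        if any(r < 0 for r in self.base_asfr_schedule):
            raise ValueError("base_asfr_schedule entries must be >= 0")
        if len(self.true_beta) != len(COVARIATE_NAMES):
            raise ValueError(
                f"true_beta needs {len(COVARIATE_NAMES)} entries "
                f"(one per covariate in {COVARIATE_NAMES})"
            )

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_extent(self.region_extent, self.cell_km)

    @property
    def tfr_base(self) -> float:
        return 5.0 * float(sum(self.base_asfr_schedule))

    @property
    def doi_cmc(self) -> int:
        # interview in June of the survey year, months since January 1900
        return (self.survey_year - 1900) * 12 + 6


# ------------------------------------------------------------------- rasters

def _smooth_unit_surface(grid: GridSpec, rng: np.random.Generator,
                         smoothness_km: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to mean 0, sd 1."""
    z = rng.standard_normal(grid.shape)
    sigma_px = max(smoothness_km / grid.cell_km, 1e-6)
    s = gaussian_filter(z, sigma=sigma_px, mode="reflect")
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def seeded_city_points(config: SimulationConfig) -> np.ndarray:
    """City locations, a deterministic function of the config seed."""
    rng = substream_rng(config.seed, "cities")
    x0, y0, x1, y1 = config.region_extent
    return np.column_stack([
        rng.uniform(x0, x1, config.n_cities),
        rng.uniform(y0, y1, config.n_cities),
    ])


def simulate_covariate_rasters(config: SimulationConfig) -> CovariateStack:
    """Generate the five covariate layers on the config grid.

    Distance layers are exact Euclidean distances (km) from each pixel
    centre to seeded city / health-facility point sets; altitude is a
    smoothed random surface; population density is a strictly positive
    log-smooth surface elevated near cities; ``prop_muslim`` is the true
    religious-proportion surface, a logistic transform of a smooth field.
    """
    grid = config.grid
    pix = grid.center_points()
    cities = seeded_city_points(config)
    rng_h = substream_rng(config.seed, "health_facilities")
    x0, y0, x1, y1 = config.region_extent
    health = np.column_stack([
        rng_h.uniform(x0, x1, config.n_health_facilities),
        rng_h.uniform(y0, y1, config.n_health_facilities),
    ])

    d_city = cdist(pix, cities).min(axis=1).reshape(grid.shape)
    d_health = cdist(pix, health).min(axis=1).reshape(grid.shape)
    # a pixel that contains a seeded point is at distance 0 by convention
    for pts, layer in ((cities, d_city), (health, d_health)):
        r, c = grid.index_of(pts[:, 0], pts[:, 1])
        inside = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
        layer[r[inside], c[inside]] = 0.0

    rng_alt = substream_rng(config.seed, "altitude")
    altitude = 1500.0 + 400.0 * _smooth_unit_surface(grid, rng_alt, config.smoothness_km)

    rng_pop = substream_rng(config.seed, "pop_density")
    s_pop = _smooth_unit_surface(grid, rng_pop, config.smoothness_km)
    pop_density = 150.0 * np.exp(0.9 * s_pop - 0.015 * d_city)

    rng_rel = substream_rng(config.seed, "prop_muslim")
    s_rel = _smooth_unit_surface(grid, rng_rel, config.smoothness_km)
    prop_muslim = 1.0 / (1.0 + np.exp(-1.2 * s_rel))

    stack = CovariateStack(grid)
    for name, vals in [
        ("travel_time_city", d_city),
        ("dist_health_facility", d_health),
        ("prop_muslim", prop_muslim),
        ("altitude", altitude),
        ("pop_density", pop_density),
    ]:
        stack.add(RasterLayer(grid, vals, name))
    return stack


def simulate_matern_field(grid: GridSpec, params: MaternParams,
                          seed: int, max_coarse: int = 50) -> RasterLayer:
    """One draw of a zero-mean Matérn Gaussian field on ``grid``.

    The field is drawn exactly (dense Cholesky) on a coarse lattice of at
    most ``max_coarse`` x ``max_coarse`` nodes spanning the grid extent,
    then refined to the full grid by bilinear interpolation.  The
    interpolation slightly smooths sub-coarse-cell variation; the coarse
    spacing should stay well below the Matérn range for a faithful draw.
    """
    if params.sigma2 < 0 or params.range_km <= 0:
        raise ValueError("need sigma2 >= 0 and range_km > 0")
    if params.sigma2 == 0:
        return RasterLayer(grid, np.zeros(grid.shape), "matern_field")
    rng = np.random.default_rng(seed)
    nr = min(max_coarse, grid.n_rows)
    nc = min(max_coarse, grid.n_cols)
    x0, y0, x1, y1 = grid.extent
    xs = np.linspace(x0, x1, nc)
    ys = np.linspace(y0, y1, nr)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    K = params.sigma2 * matern_correlation(
        cdist(nodes, nodes), params.range_km, params.nu
    )
    cf, _ = _chol_with_jitter(K)
    L = np.tril(cf[0])
    z = L @ rng.standard_normal(nodes.shape[0])
    coarse = z.reshape(nr, nc)
    if (nr, nc) == grid.shape and nr > 1 and nc > 1:
        # coarse nodes rarely coincide with pixel centres, still interpolate
        pass
    interp = RegularGridInterpolator(
        (ys, xs), coarse, method="linear", bounds_error=False, fill_value=None
    )
    Xg, Yg = grid.center_mesh()
    vals = interp(np.column_stack([Yg.ravel(), Xg.ravel()])).reshape(grid.shape)
    return RasterLayer(grid, vals, "matern_field")


# ------------------------------------------------------------------- clusters

def simulate_clusters(config: SimulationConfig) -> List[ClusterRecord]:
    """Stratified survey clusters: uniform locations, urban flag, design weight.

    The ``round(urban_fraction * n)`` clusters nearest to the seeded city
    points are urban.  Design weights mimic a two-stratum design in which
    urban areas are oversampled (raw weights 0.8 urban / 1.25 rural),
    normalized to mean exactly 1.
    """
    n = config.n_clusters
    grid = config.grid
    if n > grid.n_rows * grid.n_cols:
        raise ValueError(
            f"n_clusters = {n} exceeds the number of grid cells "
            f"({grid.n_rows * grid.n_cols})"
        )
    rng = substream_rng(config.seed, "clusters")
    x0, y0, x1, y1 = config.region_extent
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    cities = seeded_city_points(config)
    d_city = cdist(np.column_stack([xs, ys]), cities).min(axis=1)
    n_urban = int(round(config.urban_fraction * n))
    urban = np.zeros(n, dtype=bool)
    if n_urban > 0:
        urban[np.argsort(d_city, kind="stable")[:n_urban]] = True
    raw_w = np.where(urban, 0.8, 1.25)
    weights = raw_w / raw_w.mean()
    return [
        ClusterRecord(
            cluster_id=f"c{i:04d}",
            x_km=float(xs[i]),
            y_km=float(ys[i]),
            urban=bool(urban[i]),
            year=config.survey_year,
            weight=float(weights[i]),
        )
        for i in range(n)
    ]


def clusters_frame(clusters: Sequence[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "x_km": [c.x_km for c in clusters],
            "y_km": [c.y_km for c in clusters],
            "urban": [int(c.urban) for c in clusters],
            "year": [c.year for c in clusters],
            "weight": [c.weight for c in clusters],
        }
    )


# ------------------------------------------------------------- birth histories

def _age_group_window_months(dob: int, doi: int, window_months: int) -> np.ndarray:
    """(7, 2) inclusive month bounds of each age-group segment in the window.

    Segments with no overlap get lo > hi.  Mirrors the exposure logic of
    :mod:`fertimap.rates` so simulated births land exactly in the months
    the estimator attributes to each group.
    """
    w_lo, w_hi = doi - window_months + 1, doi
    seg = np.empty((N_AGE_GROUPS, 2), dtype=int)
    for a in range(N_AGE_GROUPS):
        g_lo = dob + 180 + 60 * a
        g_hi = g_lo + 60 - 1
        seg[a] = (max(w_lo, g_lo), min(w_hi, g_hi))
    return seg


def local_true_tfr(clusters: Sequence[ClusterRecord], stack: CovariateStack,
                   field: RasterLayer, config: SimulationConfig) -> np.ndarray:
    """True TFR at each cluster: intercept + beta . Xstd + mu, floored."""
    for name in COVARIATE_NAMES:
        if name not in stack:
            raise KeyError(f"covariate layer {name!r} missing from stack")
    xs = np.array([c.x_km for c in clusters])
    ys = np.array([c.y_km for c in clusters])
    lin = np.full(len(clusters), config.true_intercept, dtype=float)
    for name, beta in zip(COVARIATE_NAMES, config.true_beta):
        raw = np.asarray(stack[name].value_at(xs, ys), dtype=float)
        sd = raw.std(ddof=0)
        if sd == 0:
            continue
        lin += beta * (raw - raw.mean()) / sd
    lin += np.asarray(field.value_at(xs, ys), dtype=float)
    return np.maximum(lin, config.tfr_floor)


def simulate_birth_histories(clusters: Sequence[ClusterRecord],
                             stack: CovariateStack, field: RasterLayer,
                             config: SimulationConfig,
                             window_months: int = 36) -> List[WomanRecord]:
    """Retrospective birth histories consistent with the local fertility surface.

    Each woman's age at interview is uniform on [15, 50) years (in whole
    months); births per age-group segment of her window are Poisson with
    rate ``exposure_years * schedule[a] * TFR(s)/TFR_base`` and birth
    months uniform within the segment.  Women inherit their cluster's
    design weight.
    """
    tfr = local_true_tfr(clusters, stack, field, config)
    schedule = np.asarray(config.base_asfr_schedule)
    tfr_base = config.tfr_base
    rng = substream_rng(config.seed, "birth_histories")
    doi = config.doi_cmc
    women: List[WomanRecord] = []
    for ci, cluster in enumerate(clusters):
        scale = tfr[ci] / tfr_base
        ages = rng.integers(180, 600, size=config.women_per_cluster)
        for wi, age in enumerate(ages):
            dob = doi - int(age)
            seg = _age_group_window_months(dob, doi, window_months)
            child_dobs: List[int] = []
            for a in range(N_AGE_GROUPS):
                lo, hi = seg[a]
                months = hi - lo + 1
                if months <= 0:
                    continue
                lam = (months / 12.0) * schedule[a] * scale
                k = int(rng.poisson(lam))
                if k:
                    child_dobs.extend(int(m) for m in rng.integers(lo, hi + 1, size=k))
            women.append(
                WomanRecord(
                    woman_id=f"{cluster.cluster_id}w{wi:03d}",
                    cluster_id=cluster.cluster_id,
                    dob_cmc=dob,
                    doi_cmc=doi,
                    weight=cluster.weight,
                    child_dobs_cmc=sorted(child_dobs),
                )
            )
    return women


def women_frame(women: Sequence[WomanRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "woman_id": [w.woman_id for w in women],
            "cluster_id": [w.cluster_id for w in women],
            "dob_cmc": [w.dob_cmc for w in women],
            "doi_cmc": [w.doi_cmc for w in women],
            "weight": [w.weight for w in women],
            "child_dobs_cmc": [
                ";".join(str(c) for c in w.child_dobs_cmc) for w in women
            ],
        }
    )


def simulate_cluster_proportions(clusters: Sequence[ClusterRecord],
                                 stack: CovariateStack,
                                 config: SimulationConfig) -> pd.DataFrame:
    """Observed per-cluster proportions of Muslim women (binomial noise).

    Samples ``women_per_cluster`` Bernoulli draws per cluster from the
    true ``prop_muslim`` surface — the raw material the kriging stage
    interpolates into a covariate surface.
    """
    layer = stack["prop_muslim"]
    rng = substream_rng(config.seed, "cluster_proportions")
    rows = []
    for c in clusters:
        p = float(layer.value_at(c.x_km, c.y_km))
        k = int(rng.binomial(config.women_per_cluster, p))
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "x_km": c.x_km,
                "y_km": c.y_km,
                "proportion": k / config.women_per_cluster,
                "n_women": config.women_per_cluster,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- admin units

def _split_bounds(n_units: int, n_px: int, rng: np.random.Generator) -> np.ndarray:
    """n_units+1 pixel-boundary indices partitioning [0, n_px], jittered."""
    if n_units > n_px:
        raise ValueError(f"cannot split {n_px} pixels into {n_units} units")
    bounds = np.round(np.linspace(0, n_px, n_units + 1)).astype(int)
    slack = n_px // (4 * n_units)
    if slack > 0:
        for i in range(1, n_units):
            j = int(rng.integers(-slack, slack + 1))
            bounds[i] = int(np.clip(bounds[i] + j, bounds[i - 1] + 1, n_px - (n_units - i)))
    return bounds


def simulate_admin_units(grid: GridSpec, n_regions: int, n_zones_per_region: int,
                         seed: int, n_districts_per_zone: int = 2) -> AdminPolygons:
    """Nested rectangular partition: national > regions > zones > districts.

    Regions are vertical strips of the extent, zones horizontal strips of
    each region, districts vertical strips of each zone; all boundaries
    snap to pixel edges (jittered around even splits), so every pixel
    centre belongs to exactly one unit per level.
    """
    if n_regions < 1 or n_zones_per_region < 1 or n_districts_per_zone < 1:
        raise ValueError("unit counts must be >= 1")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = grid.extent
    cell = grid.cell_km
    units: List[AdminUnit] = [
        AdminUnit("national", "national", None, box(x0, y0, x1, y1))
    ]
    rb = _split_bounds(n_regions, grid.n_cols, rng)
    for ri in range(n_regions):
        rx0 = x0 + rb[ri] * cell
        rx1 = x0 + rb[ri + 1] * cell
        rid = f"R{ri:02d}"
        units.append(AdminUnit(rid, "region", "national", box(rx0, y0, rx1, y1)))
        zb = _split_bounds(n_zones_per_region, grid.n_rows, rng)
        for zi in range(n_zones_per_region):
            zy0 = y0 + zb[zi] * cell
            zy1 = y0 + zb[zi + 1] * cell
            zid = f"{rid}Z{zi:02d}"
            units.append(AdminUnit(zid, "zone", rid, box(rx0, zy0, rx1, zy1)))
            n_px_x = rb[ri + 1] - rb[ri]
            db = _split_bounds(n_districts_per_zone, n_px_x, rng)
            for di in range(n_districts_per_zone):
                dx0 = rx0 + db[di] * cell
                dx1 = rx0 + db[di + 1] * cell
                did = f"{zid}D{di:02d}"
                units.append(
                    AdminUnit(did, "district", zid, box(dx0, zy0, dx1, zy1))
                )
    return AdminPolygons(units)
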