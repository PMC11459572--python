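"""End-to-end orchestration: simulate -> rates -> covariates -> krige -> fit
-> predict -> aggregate -> report.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so a run can be resumed: with ``resume=True`` the pipeline
finds the earliest stage with a missing output and re-executes from there
(earlier stages are trusted as-is).  A manifest with SHA-256 checksums of
every output file is written at the end; two runs with the same config
and seed produce identical manifests.

Direct-rate trends are computed for every survey year in the config; the
geostatistical analysis (kriging covariate, model fits, prediction,
aggregation) runs on the focal year (the last one by default).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as fio
from .covariates import build_design_matrix, collinearity_check
from .geostat import ModelSpec, compare_models, fit as geostat_fit
from .grids import CovariateStack, RasterLayer
from .kriging import MaternParams, default_hyper_grid, krige_fit, krige_predict
from .prediction import aggregate, predict_pixels, range_report
from .rates import weighted_rates
from .seeding import substream_seed
from .synthetic import (
    DEFAULT_ASFR_SCHEDULE,
    DEFAULT_TRUE_BETA,
    SimulationConfig,
    simulate_admin_units,
    simulate_birth_histories,
    simulate_cluster_proportions,
    simulate_clusters,
    simulate_covariate_rasters,
    simulate_matern_field,
)

log = logging.getLogger("fertimap")

STAGES = ["simulate", "rates", "covariates", "krige", "fit", "predict",
          "aggregate", "report"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    region_extent: Tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    cell_km: float = 1.0
    n_clusters: int = 250
    urban_fraction: float = 0.2
    women_per_cluster: int = 25
    survey_years: Tuple[int, ...] = (2000, 2019)
    window_months: int = 36
    n_regions: int = 3
    n_zones_per_region: int = 2
    n_districts_per_zone: int = 2
    matern_sigma2: float = 0.25
    matern_range_km: float = 30.0
    matern_nu: float = 1.0
    true_intercept: float = 4.5
    true_beta: Tuple[float, ...] = DEFAULT_TRUE_BETA
    base_asfr_schedule: Tuple[float, ...] = DEFAULT_ASFR_SCHEDULE
    krige_grid_shape: Tuple[int, int, int] = (7, 7, 3)
    log_level: str = "INFO"

    @property
    def focal_year(self) -> int:
        return self.survey_years[-1]

    def sim_config(self, year: int) -> SimulationConfig:
        return SimulationConfig(
            region_extent=tuple(self.region_extent),
            cell_km=self.cell_km,
            n_clusters=self.n_clusters,
            urban_fraction=self.urban_fraction,
            women_per_cluster=self.women_per_cluster,
            true_beta=tuple(self.true_beta),
            true_intercept=self.true_intercept,
            matern=MaternParams(self.matern_sigma2, self.matern_range_km,
                                self.matern_nu),
            base_asfr_schedule=tuple(self.base_asfr_schedule),
            seed=substream_seed(self.seed, f"survey:{year}"),
            survey_year=year,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("region_extent", "survey_years", "true_beta",
                  "base_asfr_schedule", "krige_grid_shape"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path, out_dir: Optional[str] = None) -> "RunConfig":
        d = fio.read_yaml(path)
        d.setdefault("out_dir", out_dir or str(Path(path).parent))
        return cls.from_dict(d)


# ---------------------------------------------------------------- stage files

def _stage_outputs(cfg: RunConfig, out: Path) -> Dict[str, List[Path]]:
    sim = [out / "admin.geojson"]
    for y in cfg.survey_years:
        sim += [out / f"women_{y}.csv", out / f"clusters_{y}.csv"]
    y0 = cfg.focal_year
    cov_tifs = [out / "covariates" / f"{n}.tif"
                for n in ("travel_time_city", "dist_health_facility",
                          "prop_muslim", "altitude", "pop_density")]
    return {
        "simulate": sim + cov_tifs + [out / "matern_field.tif",
                                      out / f"props_muslim_{y0}.csv"],
        "rates": [out / "rates_by_cluster.csv", out / "national_trend.csv",
                  out / "rates_by_stratum.csv"],
        "covariates": [out / "design.csv", out / "standardization.yaml",
                       out / "collinearity.csv"],
        "krige": [out / "prop_muslim_kriged_mean.tif",
                  out / "prop_muslim_kriged_sd.tif"],
        "fit": [out / "coefficients.csv", out / "model_comparison.csv"],
        "predict": [out / f"surface_{r}_{s}.tif"
                    for r in ("tfr", "asfr")
                    for s in ("mean", "sd", "lower95", "upper95")],
        "aggregate": [out / "aggregates.csv"],
        "report": [out / "range_report.csv"],
    }


def _run_stage(name: str, cfg: RunConfig, out: Path) -> None:
    y0 = cfg.focal_year
    if name == "simulate":
        (out / "covariates").mkdir(exist_ok=True)
        for year in cfg.survey_years:
            sc = cfg.sim_config(year)
            stack = simulate_covariate_rasters(sc)
            fld = simulate_matern_field(sc.grid, sc.matern,
                                        substream_seed(sc.seed, "field"))
            clusters = simulate_clusters(sc)
            women = simulate_birth_histories(clusters, stack, fld, sc,
                                             cfg.window_months)
            fio.write_clusters_csv(clusters, out / f"clusters_{year}.csv")
            fio.write_women_csv(women, out / f"women_{year}.csv")
            if year == y0:
                for lname in stack.names:
                    fio.write_raster(stack[lname], out / "covariates" / f"{lname}.tif")
                fio.write_raster(fld, out / "matern_field.tif")
                props = simulate_cluster_proportions(clusters, stack, sc)
                props.to_csv(out / f"props_muslim_{y0}.csv", index=False)
        sc0 = cfg.sim_config(y0)
        admin = simulate_admin_units(sc0.grid, cfg.n_regions,
                                     cfg.n_zones_per_region,
                                     substream_seed(cfg.seed, "admin"),
                                     cfg.n_districts_per_zone)
        fio.write_admin_geojson(admin, out / "admin.geojson")

    elif name == "rates":
        trend_rows = []
        strat_rows = []
        for year in cfg.survey_years:
            women = fio.read_women_csv(out / f"women_{year}.csv")
            nat = weighted_rates(women, cfg.window_months)
            trend_rows.append({"year": year, "tfr": nat.tfr,
                               "summed_asfr": nat.summed_asfr,
                               "complete": nat.complete})
            clusters = fio.read_clusters_csv(out / f"clusters_{year}.csv")
            urban_ids = set(clusters.loc[clusters.urban == 1, "cluster_id"])
            for stratum, sel in (
                ("urban", [w for w in women if w.cluster_id in urban_ids]),
                ("rural", [w for w in women if w.cluster_id not in urban_ids]),
            ):
                if sel:
                    r = weighted_rates(sel, cfg.window_months)
                    strat_rows.append({"year": year, "stratum": stratum,
                                       "tfr": r.tfr,
                                       "summed_asfr": r.summed_asfr})
        pd.DataFrame(trend_rows).to_csv(out / "national_trend.csv", index=False)
        pd.DataFrame(strat_rows).to_csv(out / "rates_by_stratum.csv", index=False)

        women0 = fio.read_women_csv(out / f"women_{y0}.csv")
        by_cluster: Dict[str, list] = {}
        for w in women0:
            by_cluster.setdefault(w.cluster_id, []).append(w)
        rows = []
        for cid in sorted(by_cluster):
            r = weighted_rates(by_cluster[cid], cfg.window_months)
            rows.append({"cluster_id": cid, "tfr": r.tfr,
                         "summed_asfr": r.summed_asfr,
                         "births": r.births.sum(),
                         "woman_years": r.exposure.sum(),
                         "complete": r.complete})
        pd.DataFrame(rows).to_csv(out / "rates_by_cluster.csv", index=False)

    elif name == "covariates":
        clusters = fio.read_clusters_csv(out / f"clusters_{y0}.csv")
        stack = _load_stack(out, kriged=False)
        design, std = build_design_matrix(clusters, stack)
        design.to_csv(out / "design.csv")
        fio.write_yaml({"means": std.means, "sds": std.sds},
                       out / "standardization.yaml")
        corr, flags = collinearity_check(design)
        corr.to_csv(out / "collinearity.csv")
        if flags:
            log.warning("collinearity flags: %s", flags)

    elif name == "krige":
        props = pd.read_csv(out / f"props_muslim_{y0}.csv")
        pts = props[["x_km", "y_km"]].to_numpy()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        scale = float(np.linalg.norm(hi - lo)) or 1.0
        ns, nr, ng = cfg.krige_grid_shape
        grid_nodes = default_hyper_grid(props["proportion"].to_numpy(), scale,
                                        ns, nr, ng)
        kf = krige_fit(pts, props["proportion"].to_numpy(), grid_nodes)
        sc0 = cfg.sim_config(y0)
        mean, sd = krige_predict(kf, sc0.grid)
        mean.name = "prop_muslim"
        fio.write_raster(mean, out / "prop_muslim_kriged_mean.tif")
        fio.write_raster(sd, out / "prop_muslim_kriged_sd.tif")

    elif name == "fit":
        design, std, locations = _load_design(out, y0)
        rates_df = pd.read_csv(out / "rates_by_cluster.csv").set_index("cluster_id")
        rates_df.index = rates_df.index.astype(str)
        rates_df = rates_df.loc[design.index]
        terms = _screened_terms(design)
        coef_rows = []
        cmp_rows = []
        for response in ("tfr", "asfr"):
            yvals = rates_df["tfr" if response == "tfr" else "summed_asfr"].to_numpy()
            fits = {}
            for spatial in (True, False):
                spec = ModelSpec(response=response,
                                 linear_terms=terms,
                                 spatial=spatial)
                f = geostat_fit(spec, yvals, design, locations)
                fits[spatial] = f
                tab = f.summary()
                tab.insert(0, "response", response)
                tab.insert(1, "model", "spatial" if spatial else "nonspatial")
                coef_rows.append(tab)
                _save_fit(f, out / f"fit_{response}_{'spatial' if spatial else 'nonspatial'}.npz")
            cm = compare_models(fits[True], fits[False])
            cmp_rows.append({"response": response,
                             "delta_log_marginal": cm.delta_log_marginal,
                             "preferred": cm.preferred})
        pd.concat(coef_rows, ignore_index=True).to_csv(
            out / "coefficients.csv", index=False)
        pd.DataFrame(cmp_rows).to_csv(out / "model_comparison.csv", index=False)

    elif name == "predict":
        design, std, locations = _load_design(out, y0)
        rates_df = pd.read_csv(out / "rates_by_cluster.csv").set_index("cluster_id")
        rates_df.index = rates_df.index.astype(str)
        rates_df = rates_df.loc[design.index]
        stack = _load_stack(out, kriged=True)
        terms = _screened_terms(design)
        for response in ("tfr", "asfr"):
            yvals = rates_df["tfr" if response == "tfr" else "summed_asfr"].to_numpy()
            spec = ModelSpec(response=response,
                             linear_terms=terms, spatial=True)
            f = geostat_fit(spec, yvals, design, locations)
            surf = predict_pixels(f, stack, std)
            for sname, layer in (("mean", surf.mean), ("sd", surf.sd),
                                 ("lower95", surf.lower95),
                                 ("upper95", surf.upper95)):
                fio.write_raster(layer, out / f"surface_{response}_{sname}.tif")

    elif name == "aggregate":
        admin = fio.read_admin_geojson(out / "admin.geojson")
        pop = fio.read_raster(out / "covariates" / "pop_density.tif")
        tables = []
        for response in ("tfr", "asfr"):
            surf = _load_surface(out, response)
            tab = aggregate(surf, admin, pop)
            tab.insert(0, "response", response)
            tables.append(tab)
        pd.concat(tables, ignore_index=True).to_csv(out / "aggregates.csv",
                                                    index=False)

    elif name == "report":
        agg = pd.read_csv(out / "aggregates.csv")
        reports = []
        for response, sub in agg.groupby("response", sort=False):
            surf = _load_surface(out, response)
            rep = range_report(sub, surf)
            rep.insert(0, "response", response)
            reports.append(rep)
        pd.concat(reports, ignore_index=True).to_csv(out / "range_report.csv",
                                                     index=False)
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {name!r}")


def _screened_terms(design: pd.DataFrame) -> List[str]:
    """Covariates passing the |r| < 0.7 screen.

    From every flagged pair the later-listed covariate is dropped (greedy,
    deterministic), mirroring the practice of selecting a covariate set
    whose pairwise correlations all stay below the threshold.
    """
    _, flags = collinearity_check(design)
    drop: set = set()
    for a, b, r in flags:
        if a in drop or b in drop:
            continue
        drop.add(b)
        log.warning("dropping covariate %r (|r|=%.2f with %r)", b, abs(r), a)
    return [c for c in design.columns if c not in drop]


def _load_stack(out: Path, kriged: bool) -> CovariateStack:
    names = ["travel_time_city", "dist_health_facility", "prop_muslim",
             "altitude", "pop_density"]
    layers = {}
    for n in names:
        if kriged and n == "prop_muslim":
            layer = fio.read_raster(out / "prop_muslim_kriged_mean.tif")
            layer.name = "prop_muslim"
        else:
            layer = fio.read_raster(out / "covariates" / f"{n}.tif")
        layers[n] = layer
    return CovariateStack(layers["altitude"].grid, layers)


def _load_design(out: Path, year: int):
    from .covariates import Standardization

    design = pd.read_csv(out / "design.csv").set_index("cluster_id")
    design.index = design.index.astype(str)
    sdict = fio.read_yaml(out / "standardization.yaml")
    std = Standardization(sdict["means"], sdict["sds"])
    clusters = fio.read_clusters_csv(out / f"clusters_{year}.csv")
    clusters = clusters.set_index("cluster_id").loc[design.index]
    locations = clusters[["x_km", "y_km"]].to_numpy()
    return design, std, locations


def _load_surface(out: Path, response: str):
    from .prediction import PredictionSurface

    layers = {s: fio.read_raster(out / f"surface_{response}_{s}.tif")
              for s in ("mean", "sd", "lower95", "upper95")}
    return PredictionSurface(layers["mean"].grid, layers["mean"], layers["sd"],
                             layers["lower95"], layers["upper95"], response)


def _save_fit(f, path: Path) -> None:
    """Persist the fixed-effect summary of a fit (full state stays in memory)."""
    f.summary().to_csv(path.with_suffix(".csv"), index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_all(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    With ``resume=True`` the earliest stage with any missing output is
    located and execution restarts there; earlier stages are reused.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    archived = cfg.to_dict()
    archived.pop("out_dir")  # implicit: the directory the archive sits in
    fio.write_yaml(archived, out / "config.yaml")

    outputs = _stage_outputs(cfg, out)
    start = 0
    if resume:
        for i, stage in enumerate(STAGES):
            if not all(p.exists() for p in outputs[stage]):
                start = i
                break
        else:
            start = len(STAGES)

    for stage in STAGES[start:]:
        log.info("stage: %s", stage)
        try:
            _run_stage(stage, cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        missing = [p for p in outputs[stage] if not p.exists()]
        if missing:  # pragma: no cover - internal consistency check
            raise RuntimeError(f"stage {stage!r} did not produce {missing}")

    manifest = {"config": cfg.to_dict(), "checksums": {}}
    for stage in STAGES:
        for p in outputs[stage]:
            manifest["checksums"][str(p.relative_to(out))] = _sha256(p)
    manifest["checksums"]["config.yaml"] = _sha256(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
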