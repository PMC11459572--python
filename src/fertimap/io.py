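"""Readers and writers for the package's on-disk formats.

* women / clusters / rates / design / aggregation tables: CSV via pandas;
* rasters: single-band float32 TIFF via tifffile, nodata -9999, with the
  grid geometry (origin, cell size, shape) serialized as JSON in the
  ImageDescription tag so files are self-describing;
* admin units: GeoJSON FeatureCollection with ``id``, ``level`` and
  ``parent_id`` properties;
* configuration: YAML.

Round-trips preserve values exactly up to the float32 quantization of
raster cells.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from .admin import AdminPolygons, AdminUnit
from .grids import NODATA, GridSpec, RasterLayer
from .rates import WomanRecord
from .synthetic import ClusterRecord

PathLike = Union[str, Path]


# -------------------------------------------------------------------- tables

def write_women_csv(women, path: PathLike) -> None:
    from .synthetic import women_frame

    women_frame(women).to_csv(path, index=False)


def read_women_csv(path: PathLike) -> List[WomanRecord]:
    try:
        df = pd.read_csv(path, dtype={"child_dobs_cmc": str})
    except Exception as exc:  # pragma: no cover - pandas gives the context
        raise ValueError(f"malformed women CSV {path}: {exc}") from exc
    required = {"woman_id", "cluster_id", "dob_cmc", "doi_cmc", "weight",
                "child_dobs_cmc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"women CSV {path} lacks column(s) {sorted(missing)}")
    women = []
    for i, row in enumerate(df.itertuples()):
        raw = row.child_dobs_cmc
        kids = [] if pd.isna(raw) or raw == "" else [int(v) for v in str(raw).split(";")]
        try:
            women.append(
                WomanRecord(str(row.woman_id), str(row.cluster_id),
                            int(row.dob_cmc), int(row.doi_cmc),
                            float(row.weight), kids)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"women CSV {path}, data row {i + 1}: {exc}") from exc
    return women


def write_clusters_csv(clusters, path: PathLike) -> None:
    from .synthetic import clusters_frame

    clusters_frame(clusters).to_csv(path, index=False)


def read_clusters_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cluster_id", "x_km", "y_km", "urban", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clusters CSV {path} lacks column(s) {sorted(missing)}")
    df["cluster_id"] = df["cluster_id"].astype(str)
    return df


def clusters_from_frame(df: pd.DataFrame) -> List[ClusterRecord]:
    return [
        ClusterRecord(str(r.cluster_id), float(r.x_km), float(r.y_km),
                      bool(r.urban), int(r.year),
                      float(getattr(r, "weight", 1.0)))
        for r in df.itertuples()
    ]


# -------------------------------------------------------------------- rasters

def write_raster(layer: RasterLayer, path: PathLike) -> None:
    """Single-band float32 TIFF; nan becomes the nodata value -9999."""
    g = layer.grid
    meta = {
        "x_origin": g.x_origin,
        "y_origin": g.y_origin,
        "cell_km": g.cell_km,
        "nodata": NODATA,
        "name": layer.name,
    }
    vals = np.where(np.isfinite(layer.values), layer.values, NODATA)
    tifffile.imwrite(path, vals.astype(np.float32),
                     description=json.dumps(meta))


def read_raster(path: PathLike) -> RasterLayer:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        desc = page.description or ""
        vals = page.asarray().astype(float)
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"raster {path} has no grid metadata in its description tag"
        ) from exc
    grid = GridSpec(
        float(meta["x_origin"]), float(meta["y_origin"]), float(meta["cell_km"]),
        vals.shape[0], vals.shape[1],
    )
    nodata = float(meta.get("nodata", NODATA))
    vals[vals == nodata] = np.nan
    return RasterLayer(grid, vals, str(meta.get("name", Path(path).stem)))


# -------------------------------------------------------------------- geojson

def write_admin_geojson(admin: AdminPolygons, path: PathLike) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "id": u.unit_id,
                "level": u.level,
                "parent_id": u.parent_id,
            },
            "geometry": shapely_mapping(u.polygon),
        }
        for u in admin.units
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_admin_geojson(path: PathLike) -> AdminPolygons:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    units = []
    for i, feat in enumerate(data.get("features", [])):
        try:
            props = feat["properties"]
            units.append(
                AdminUnit(str(props["id"]), str(props["level"]),
                          props.get("parent_id"),
                          shapely_shape(feat["geometry"]))
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed feature #{i}: {exc}") from exc
    return AdminPolygons(units)


# ----------------------------------------------------------------------- yaml

def write_yaml(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: PathLike):
    with open(path) as fh:
        return yaml.safe_load(fh)
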