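"""Covariate raster harmonization and design-matrix construction.

Rasters of differing resolution are brought onto a common ~1 km grid
(area-weighted aggregation when coarsening, bilinear interpolation when
refining), clipped to the study extent, and summarized at cluster
locations as buffer means — 2 km radius for urban clusters and 5 km for
rural ones, absorbing the positional displacement applied to survey
cluster coordinates.  Buffer membership is decided by pixel centre.

The design matrix holds one standardized column (mean 0, sd 1 over the
cluster sample) per covariate; the standardization constants are recorded
so pixel-level prediction reuses the training-time scaling.  A Pearson
correlation screen flags covariate pairs at |r| >= 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grids import CovariateStack, Extent, GridSpec, RasterLayer

__all__ = [
    "URBAN_BUFFER_KM",
    "RURAL_BUFFER_KM",
    "COLLINEARITY_THRESHOLD",
    "Standardization",
    "resample_to_grid",
    "clip",
    "buffer_extract",
    "build_design_matrix",
    "collinearity_check",
]

URBAN_BUFFER_KM = 2.0
RURAL_BUFFER_KM = 5.0
#: pairs with |Pearson r| at or above this are flagged as collinear
COLLINEARITY_THRESHOLD = 0.7


# ------------------------------------------------------------------ resampling

def _axis_overlap(src_origin, src_cell, src_n, dst_origin, dst_cell, dst_n):
    """(dst_n, src_n) matrix of 1-D interval overlap lengths."""
    src_lo = src_origin + src_cell * np.arange(src_n)
    dst_lo = dst_origin + dst_cell * np.arange(dst_n)
    lo = np.maximum(dst_lo[:, None], src_lo[None, :])
    hi = np.minimum(dst_lo[:, None] + dst_cell, src_lo[None, :] + src_cell)
    return np.maximum(hi - lo, 0.0)


def resample_to_grid(src: RasterLayer, target: GridSpec) -> RasterLayer:
    """Resample ``src`` onto ``target``.

    Coarsening (target cell >= source cell) uses the area-weighted mean of
    contributing source cells; refining uses bilinear interpolation of
    source cell centres.  Nodata (nan) cells are excluded from means; a
    target cell with no valid contribution becomes nodata.  A source
    already conforming to ``target`` is returned as a bit-identical copy.
    """
    if src.grid == target:
        return src.copy()
    sx0, sy0, sx1, sy1 = src.grid.extent
    tx0, ty0, tx1, ty1 = target.extent
    if sx1 <= tx0 or sx0 >= tx1 or sy1 <= ty0 or sy0 >= ty1:
        raise ValueError("source and target extents are disjoint")

    if target.cell_km >= src.grid.cell_km:
        Wy = _axis_overlap(src.grid.y_origin, src.grid.cell_km, src.grid.n_rows,
                           target.y_origin, target.cell_km, target.n_rows)
        Wx = _axis_overlap(src.grid.x_origin, src.grid.cell_km, src.grid.n_cols,
                           target.x_origin, target.cell_km, target.n_cols)
        valid = np.isfinite(src.values)
        vals = np.where(valid, src.values, 0.0)
        num = Wy @ vals @ Wx.T
        den = Wy @ valid.astype(float) @ Wx.T
        out = np.full(target.shape, np.nan)
        np.divide(num, den, out=out, where=den > 0)
    else:
        interp = RegularGridInterpolator(
            (src.grid.y_centers(), src.grid.x_centers()),
            src.values, method="linear", bounds_error=False, fill_value=None,
        )
        X, Y = target.center_mesh()
        out = interp(np.column_stack([Y.ravel(), X.ravel()])).reshape(target.shape)
    return RasterLayer(target, out, src.name)


def clip(src: RasterLayer, extent: Extent) -> RasterLayer:
    """Drop cells whose centres fall outside ``extent``; origin is updated."""
    x0, y0, x1, y1 = extent
    xs = src.grid.x_centers()
    ys = src.grid.y_centers()
    cols = np.nonzero((xs >= x0) & (xs < x1))[0]
    rows = np.nonzero((ys >= y0) & (ys < y1))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("clip extent contains no cell centres")
    g = src.grid
    new_grid = GridSpec(
        g.x_origin + cols[0] * g.cell_km,
        g.y_origin + rows[0] * g.cell_km,
        g.cell_km, rows.size, cols.size,
    )
    return RasterLayer(new_grid, src.values[np.ix_(rows, cols)].copy(), src.name)


# ------------------------------------------------------------------ extraction

def buffer_extract(layer: RasterLayer, x: float, y: float, urban: bool) -> float:
    """Mean of cells whose centres lie within the stratum buffer of (x, y).

    Radius is 2 km for urban and 5 km for rural points.  If no cell
    centre falls inside the buffer the nearest cell's value is used and a
    warning is emitted.
    """
    if not bool(np.all(layer.grid.contains(x, y))):
        raise ValueError(f"point ({x}, {y}) outside raster extent")
    radius = URBAN_BUFFER_KM if urban else RURAL_BUFFER_KM
    g = layer.grid
    xs = g.x_centers()
    ys = g.y_centers()
    # restrict to the bounding square before the circular test
    ci = np.nonzero(np.abs(xs - x) <= radius)[0]
    ri = np.nonzero(np.abs(ys - y) <= radius)[0]
    if ci.size and ri.size:
        dx = xs[ci] - x
        dy = ys[ri] - y
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        sub = layer.values[np.ix_(ri, ci)]
        mask = (d2 <= radius ** 2) & np.isfinite(sub)
        if mask.any():
            return float(sub[mask].mean())
    warnings.warn(
        f"no cell centre within {radius} km of ({x}, {y}); "
        "falling back to nearest cell", stacklevel=2,
    )
    r = int(np.clip(np.argmin(np.abs(ys - y)), 0, g.n_rows - 1))
    c = int(np.clip(np.argmin(np.abs(xs - x)), 0, g.n_cols - 1))
    return float(layer.values[r, c])


# ---------------------------------------------------------------- design matrix

@dataclass
class Standardization:
    """Per-column (mean, sd) recorded at training time for reuse at prediction."""

    means: Dict[str, float]
    sds: Dict[str, float]

    def apply(self, name: str, values):
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]

    def invert(self, name: str, values):
        return np.asarray(values, dtype=float) * self.sds[name] + self.means[name]


def build_design_matrix(clusters: pd.DataFrame, stack: CovariateStack,
                        ) -> Tuple[pd.DataFrame, Standardization]:
    """Standardized cluster-by-covariate design matrix via buffer extraction.

    ``clusters`` needs columns ``cluster_id``, ``x_km``, ``y_km`` and
    ``urban``.  Returns a DataFrame indexed by cluster_id with one
    standardized column per stack layer, plus the standardization record.
    """
    cols: Dict[str, np.ndarray] = {}
    means: Dict[str, float] = {}
    sds: Dict[str, float] = {}
    for name in stack.names:
        layer = stack[name]
        raw = np.array([
            buffer_extract(layer, row.x_km, row.y_km, bool(row.urban))
            for row in clusters.itertuples()
        ])
        mu = float(raw.mean())
        sd = float(raw.std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate layer {name!r} has zero variance at clusters")
        cols[name] = (raw - mu) / sd
        means[name] = mu
        sds[name] = sd
    design = pd.DataFrame(cols, index=pd.Index(clusters["cluster_id"], name="cluster_id"))
    return design, Standardization(means, sds)


def collinearity_check(design: pd.DataFrame,
                       threshold: float = COLLINEARITY_THRESHOLD,
                       ) -> Tuple[pd.DataFrame, List[Tuple[str, str, float]]]:
    """Pearson correlation matrix with flags for |r| >= ``threshold``.

    The flag is inclusive at the threshold: the screening rule passes only
    pairs strictly below it.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least two covariate columns")
    sds = design.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    corr = design.corr()
    flags = []
    names = list(design.columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= threshold:
                flags.append((a, b, r))
    return corr, flags
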