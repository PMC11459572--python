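"""Grid and raster containers for a flat, projected-km world.

All spatial data in this package lives on axis-aligned rectangular grids in
a projected plane measured in kilometres.  The convention, fixed once here
and used everywhere:

* ``x`` increases eastward, ``y`` increases **southward** (row 0 is the
  northmost row), so the grid origin is the north-west corner of the raster.
* The centre of pixel ``(r, c)`` is ``(x_origin + (c + 0.5) * cell_km,
  y_origin + (r + 0.5) * cell_km)``.

Distances are Euclidean, so the flipped y axis is purely a bookkeeping
convention; users of real data must project to a planar CRS first.

Missing values are represented as ``nan`` in memory and as ``-9999`` on
disk (see :mod:`fertimap.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

#: (x_min, y_min, x_max, y_max) rectangle in projected km.
Extent = Tuple[float, float, float, float]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    Parameters
    ----------
    x_origin, y_origin
        North-west corner of the grid, km.
    cell_km
        Side length of the square pixels, km. Must be positive.
    n_rows, n_cols
        Raster shape; row 0 is the northmost row.
    """

    x_origin: float
    y_origin: float
    cell_km: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_km <= 0:
            raise ValueError(f"cell_km must be positive, got {self.cell_km}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> Extent:
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.n_cols * self.cell_km,
            self.y_origin + self.n_rows * self.cell_km,
        )

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_km

    def y_centers(self) -> np.ndarray:
        return self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_km

    def center_mesh(self) -> Tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of pixel-centre coordinates, shape (n_rows, n_cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def center_points(self) -> np.ndarray:
        """Pixel centres as an (n_rows*n_cols, 2) array, row-major order."""
        X, Y = self.center_mesh()
        return np.column_stack([X.ravel(), Y.ravel()])

    def index_of(self, x, y) -> Tuple[np.ndarray, np.ndarray]:
        """(row, col) of the pixel containing each point; no bounds check."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_km).astype(int)
        row = np.floor((np.asarray(y) - self.y_origin) / self.cell_km).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        x0, y0, x1, y1 = self.extent
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    @classmethod
    def from_extent(cls, extent: Extent, cell_km: float) -> "GridSpec":
        x0, y0, x1, y1 = extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"degenerate extent {extent}: zero or negative area")
        n_cols = int(round((x1 - x0) / cell_km))
        n_rows = int(round((y1 - y0) / cell_km))
        return cls(x0, y0, cell_km, max(n_rows, 1), max(n_cols, 1))


@dataclass
class RasterLayer:
    """A single gridded surface: a :class:`GridSpec` plus a float array.

    ``values`` has shape ``grid.shape``; missing cells are ``nan``.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.name)

    def value_at(self, x, y):
        """Value of the pixel containing (x, y); points must be inside."""
        inside = self.grid.contains(x, y)
        if not np.all(inside):
            raise ValueError("point(s) outside raster extent")
        r, c = self.grid.index_of(x, y)
        return self.values[r, c]


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid exactly."""

    grid: GridSpec
    layers: Dict[str, RasterLayer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if layer.grid != self.grid:
                raise ValueError(f"layer {name!r} is not on the stack grid")

    def add(self, layer: RasterLayer) -> None:
        if layer.grid != self.grid:
            raise ValueError(f"layer {layer.name!r} is not on the stack grid")
        self.layers[layer.name] = layer

    def __getitem__(self, name: str) -> RasterLayer:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"covariate layer {name!r} missing from stack "
                f"(have: {sorted(self.layers)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    @property
    def names(self):
        return list(self.layers)
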