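"""Nested administrative units (national / region / zone / district).

Units are stored with shapely polygons; the synthetic generator produces
axis-aligned rectangles that partition the study extent exactly at each
level, nested so every district lies in exactly one zone and every zone
in exactly one region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import shapely
from shapely.geometry import Polygon

LEVELS = ("national", "region", "zone", "district")


@dataclass
class AdminUnit:
    unit_id: str
    level: str
    parent_id: Optional[str]
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown admin level {self.level!r}")


@dataclass
class AdminPolygons:
    """All admin units across levels, with parent links."""

    units: List[AdminUnit] = field(default_factory=list)

    def at_level(self, level: str) -> List[AdminUnit]:
        if level not in LEVELS:
            raise ValueError(f"unknown admin level {level!r}")
        return [u for u in self.units if u.level == level]

    def by_id(self) -> Dict[str, AdminUnit]:
        return {u.unit_id: u for u in self.units}

    def parent_of(self, unit_id: str) -> Optional[AdminUnit]:
        lookup = self.by_id()
        pid = lookup[unit_id].parent_id
        return lookup[pid] if pid is not None else None

    def assign_points(self, level: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Unit id per point at ``level``; '' for points in no unit.

        Membership is by point-in-polygon with a tie-break toward the
        first unit covering the point, so border points belong to exactly
        one unit.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, "", dtype=object)
        unassigned = np.ones(x.shape, dtype=bool)
        for u in self.at_level(level):
            if not unassigned.any():
                break
            hit = shapely.contains_xy(u.polygon, x, y) & unassigned
            # include points on the boundary that strict containment missed
            border = shapely.intersects_xy(u.polygon, x, y) & unassigned & ~hit
            hit |= border
            out[hit] = u.unit_id
            unassigned &= ~hit
        return out
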