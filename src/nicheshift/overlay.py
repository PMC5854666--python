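"""Protected-area x grid overlay.

Resolves each protected-area polygon to its covering cell set (cells it
intersects with positive area), flags single-cell containment, aggregates
per-cell species maps over the covering cells ("smallest containing
polygon" = the union of covering cells), and accounts protected land area
per cell as the geometric union of all footprints clipped to the cell so
overlapping areas are never double counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union
from shapely.validation import make_valid

from .grid import LandscapeGrid
from .synthetic import ProtectedArea

log = logging.getLogger(__name__)

# positive-area intersection test: boundary touching has zero area and must
# not count; this epsilon only guards floating-point dust on shared edges
_AREA_EPS = 1e-9


def _candidate_cells(polygon, grid: LandscapeGrid) -> np.ndarray:
    """Cells whose bounding row/col window overlaps the polygon's bounds."""
    x0, y0, x1, y1 = polygon.bounds
    gx0, gy0, gx1, gy1 = grid.extent
    if x1 <= gx0 or x0 >= gx1 or y1 <= gy0 or y0 >= gy1:
        return np.empty(0, dtype=int)
    s = grid.cell_size
    c0 = max(0, int((x0 - gx0) // s))
    c1 = min(grid.n_cols - 1, int(np.ceil((x1 - gx0) / s)) )
    r0 = max(0, int((y0 - gy0) // s))
    r1 = min(grid.n_rows - 1, int(np.ceil((y1 - gy0) / s)) )
    ids = [grid.cell_id(r, c)
           for r in range(r0, r1 + 1) for c in range(c0, min(c1, grid.n_cols - 1) + 1)]
    return np.asarray(ids, dtype=int)


def covering_cells(polygon, grid: LandscapeGrid) -> np.ndarray:
    """Ids of cells intersecting the polygon with positive area.

    Boundary-touching (zero-area) contact does not count; together with the
    half-open cell convention this assigns an area fragment to exactly one
    cell. A polygon wholly outside the extent yields an empty set with a
    warning.
    """
    cells = [cid for cid in _candidate_cells(polygon, grid)
             if grid.cell_polygon(cid).intersection(polygon).area > _AREA_EPS]
    if not cells:
        log.warning("polygon %s does not overlap the grid extent",
                    polygon.bounds)
        return np.empty(0, dtype=int)
    return np.asarray(sorted(cells), dtype=int)


def repair_polygon(polygon, pa_id: str = "?"):
    """Repair an invalid (e.g. self-intersecting) polygon or reject it."""
    if polygon.is_valid:
        return polygon
    fixed = make_valid(polygon)
    if fixed.is_valid and fixed.area > 0:
        log.warning("protected area %s: invalid polygon repaired", pa_id)
        return fixed
    raise ValueError(f"protected area {pa_id}: polygon cannot be repaired")


@dataclass
class OverlayIndex:
    """Resolved overlay of a protected-area set on the grid."""

    grid: LandscapeGrid
    covering: dict[str, np.ndarray]          # pa_id -> covering cell ids
    single_cell: dict[str, bool]             # pa_id -> contained in one cell
    protected_land: np.ndarray               # per-cell protected area (km^2)
    dropped: tuple[str, ...] = ()            # PAs outside the extent

    def cells_of(self, pa_id: str) -> np.ndarray:
        return self.covering[pa_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"pa_id": pid, "n_cells": c.size, "single_cell":
              self.single_cell[pid],
              "cell_ids": ";".join(map(str, c.tolist()))}
             for pid, c in self.covering.items()])

    def protected_land_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": np.arange(self.grid.n_cells),
                             "protected_km2": self.protected_land})


def build_overlay(areas: list[ProtectedArea],
                  grid: LandscapeGrid) -> OverlayIndex:
    """Covering cells per PA and protected-land-per-cell accounting."""
    covering: dict[str, np.ndarray] = {}
    single: dict[str, bool] = {}
    dropped: list[str] = []
    polygons = []
    for pa in areas:
        poly = repair_polygon(pa.polygon, pa.pa_id)
        cells = covering_cells(poly, grid)
        if cells.size == 0:
            dropped.append(pa.pa_id)
            continue
        covering[pa.pa_id] = cells
        single[pa.pa_id] = cells.size == 1
        polygons.append(poly)
    protected = protected_land_per_cell(polygons, grid)
    return OverlayIndex(grid=grid, covering=covering, single_cell=single,
                        protected_land=protected, dropped=tuple(dropped))


def protected_land_per_cell(polygons: list, grid: LandscapeGrid
                            ) -> np.ndarray:
    """Per-cell area of the union of all footprints clipped to the cell.

    Union semantics: land covered by several overlapping protected areas is
    counted once. Result is in the grid's squared length unit (km^2).
    """
    out = np.zeros(grid.n_cells)
    if not polygons:
        return out
    union = unary_union(polygons)
    for cid in covering_cells(union, grid):
        inter = grid.cell_polygon(cid).intersection(union)
        out[cid] = min(inter.area, grid.cell_area)
    return out


@dataclass(frozen=True)
class PoolChange:
    """Species-pool bookkeeping over one cell set, reference vs future."""

    gain: int          # G: species entering the pool
    loss: int          # L: species leaving the pool
    ref_richness: int  # refSR
    future_richness: int

    def __post_init__(self) -> None:
        if self.future_richness != (self.ref_richness + self.gain
                                    - self.loss):
            raise ValueError("richness identity violated")


def aggregate_cell_values(cells: np.ndarray,
                          ref_presence: pd.DataFrame,
                          fut_presence: pd.DataFrame) -> PoolChange:
    """Pool species over a PA's covering cells and difference the pools.

    A species belongs to a period's pool if it is present in at least one
    covering cell. For a single-cell PA this reduces exactly to that cell's
    values. ``ref_presence`` / ``fut_presence`` are species x cells binary
    matrices sharing an index.
    """
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise ValueError("covering cell set is empty")
    in_ref = ref_presence.iloc[:, cells].to_numpy().any(axis=1)
    in_fut = fut_presence.iloc[:, cells].to_numpy().any(axis=1)
    gain = int((in_fut & ~in_ref).sum())
    loss = int((in_ref & ~in_fut).sum())
    ref_sr = int(in_ref.sum())
    return PoolChange(gain=gain, loss=loss, ref_richness=ref_sr,
                      future_richness=ref_sr + gain - loss)
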