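"""Regular square-cell landscape grid.

The grid is the common spatial frame for every layer in the pipeline:
climate variables, species suitability/presence maps, protected land and
the region hierarchy are all per-cell vectors indexed by cell id.

Conventions (fixed, documented here once):

* Planar abstract coordinates, no CRS. ``cell_size`` is a nominal length
  in km; cell area is ``cell_size ** 2`` km^2.
* Cell ids are row-major: ``cell_id = row * n_cols + col``.
* Row index increases *southward*: row 0 is the northernmost band, so
  "latitude" corresponds to decreasing row index. The y coordinate also
  increases southward (``y = origin_y + row * cell_size``).
* Cell squares are half-open in both axes, ``[x0, x0+s) x [y0, y0+s)``,
  so a point on a shared edge belongs to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box


@dataclass(frozen=True)
class LandscapeGrid:
    """A regular grid of axis-aligned square cells tiling a rectangle."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the whole grid."""
        x0, y0 = self.origin
        return (x0, y0,
                x0 + self.n_cols * self.cell_size,
                y0 + self.n_rows * self.cell_size)

    # -- id <-> (row, col) bijection -------------------------------------

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        if not (0 <= cell_id < self.n_cells):
            raise ValueError(f"cell id {cell_id} outside grid")
        return divmod(cell_id, self.n_cols)

    def rows(self) -> np.ndarray:
        """Row index of every cell, in cell-id order."""
        return np.arange(self.n_cells) // self.n_cols

    def cols(self) -> np.ndarray:
        return np.arange(self.n_cells) % self.n_cols

    # -- geometry ---------------------------------------------------------

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        row, col = self.rowcol(cell_id)
        x0 = self.origin[0] + col * self.cell_size
        y0 = self.origin[1] + row * self.cell_size
        return (x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def cell_polygon(self, cell_id: int):
        """Closed shapely box for the cell (geometry ops only; point
        membership uses the half-open rule in :meth:`point_to_cell`)."""
        return box(*self.cell_bounds(cell_id))

    def cell_centres(self) -> np.ndarray:
        """(n_cells, 2) array of cell centre coordinates."""
        half = self.cell_size / 2.0
        xs = self.origin[0] + self.cols() * self.cell_size + half
        ys = self.origin[1] + self.rows() * self.cell_size + half
        return np.column_stack([xs, ys])

    def point_to_cell(self, x: float, y: float) -> int:
        """Cell containing a point under half-open boundaries.

        Points on the far (east/south) outer boundary are outside.
        """
        x0, y0, x1, y1 = self.extent
        if not (x0 <= x < x1 and y0 <= y < y1):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        col = int((x - x0) // self.cell_size)
        row = int((y - y0) // self.cell_size)
        return self.cell_id(row, col)

    def northern_band(self, fraction: float = 1 / 3) -> np.ndarray:
        """Cell ids of the northernmost ``fraction`` of rows."""
        cut = max(1, int(round(self.n_rows * fraction)))
        return np.flatnonzero(self.rows() < cut)

    def southern_band(self, fraction: float = 1 / 3) -> np.ndarray:
        cut = max(1, int(round(self.n_rows * fraction)))
        return np.flatnonzero(self.rows() >= self.n_rows - cut)


def make_grid(n_rows: int, n_cols: int, cell_size: float,
              origin: tuple[float, float] = (0.0, 0.0)) -> LandscapeGrid:
    """Build a :class:`LandscapeGrid`; thin validated constructor."""
    return LandscapeGrid(int(n_rows), int(n_cols), float(cell_size), origin)
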