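"""Grid geometry shared by every raster in the toolkit.

Conventions (fixed once, used everywhere):

* Arrays are stored row 0 = northernmost row, matching the on-disk order of
  an ESRI ASCII grid.
* ``origin_x, origin_y`` locate the **lower-left corner** of the grid
  (``xllcorner`` / ``yllcorner`` of the ASCII header).
* A point belongs to the cell whose half-open footprint
  ``[left, right) x [bottom, top)`` contains it, so points on the shared
  edge of two cells go to the cell on the right / on top, and points on the
  far right / top edge of the grid are outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, OutOfBoundsError

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled raster grid."""

    nrows: int
    ncols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ConfigError(f"grid must have positive shape, got {self.nrows}x{self.ncols}")
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size must be positive, got {self.cell_size}")

    # -- extent ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def xmin(self) -> float:
        return self.origin_x

    @property
    def xmax(self) -> float:
        return self.origin_x + self.ncols * self.cell_size

    @property
    def ymin(self) -> float:
        return self.origin_y

    @property
    def ymax(self) -> float:
        return self.origin_y + self.nrows * self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    # -- coordinate transforms ------------------------------------------
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate vectors; y follows array row order (north first)."""
        cs = self.cell_size
        x = self.origin_x + (np.arange(self.ncols) + 0.5) * cs
        y = self.origin_y + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return x, y

    def rowcol(self, x, y):
        """Array (row, col) of the cells containing map points ``(x, y)``.

        Raises :class:`OutOfBoundsError` listing offending indices if any
        point falls outside the extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_s = np.floor((y - self.origin_y) / self.cell_size).astype(int)  # from south
        bad = (col < 0) | (col >= self.ncols) | (row_s < 0) | (row_s >= self.nrows)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))
            raise OutOfBoundsError(f"points outside grid extent at indices {idx.tolist()}")
        row = self.nrows - 1 - row_s
        return row, col

    def xy(self, row, col):
        """Map coordinates of the centers of cells at array (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def same_geometry(self, other: "GridSpec", rtol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.cell_size, other.cell_size, rtol=rtol)
            and np.isclose(self.origin_x, other.origin_x, rtol=rtol, atol=1e-9)
            and np.isclose(self.origin_y, other.origin_y, rtol=rtol, atol=1e-9)
        )

    def refine(self, factor: int) -> "GridSpec":
        """Grid covering the same extent with ``factor``-times finer cells."""
        if factor < 1 or int(factor) != factor:
            raise ConfigError(f"refinement factor must be a positive integer, got {factor}")
        return GridSpec(
            nrows=self.nrows * factor,
            ncols=self.ncols * factor,
            cell_size=self.cell_size / factor,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            nodata=self.nodata,
        )
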