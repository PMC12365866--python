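"""Planar landscape grids.

All coordinates are planar, in meters (projected data assumed; no
geographic-CRS math). Arrays are indexed ``[row, col]`` with row 0 at the
*southern* edge, so the center of pixel ``(r, c)`` is
``(x0 + (c + 0.5) * pixel_size, y0 + (r + 0.5) * pixel_size)``.
Rasters are flipped to north-up only at file I/O time (see :mod:`firesev.io`).
Pixel membership is half-open: the west and south edges of a pixel are
inclusive, the east and north edges belong to the neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LandscapeGrid:
    """A rectangular raster grid of square pixels.

    Parameters
    ----------
    x0, y0:
        Coordinates (m) of the south-west corner of the grid.
    n_rows, n_cols:
        Grid dimensions. Row 0 is the southernmost row.
    pixel_size:
        Pixel edge length in meters (default 30, the Landsat/LiDAR
        analysis resolution).
    """

    x0: float
    y0: float
    n_rows: int
    n_cols: int
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        return self.n_cols * self.pixel_size

    @property
    def height(self) -> float:
        return self.n_rows * self.pixel_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in meters."""
        return (self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 1e4

    def col_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.pixel_size

    def row_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_rows) + 0.5) * self.pixel_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays X, Y of pixel-center coordinates, shape ``(n_rows, n_cols)``."""
        X, Y = np.meshgrid(self.col_centers(), self.row_centers())
        return X, Y

    # -- point membership -------------------------------------------------

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        xmin, ymin, xmax, ymax = self.extent
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def pixel_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Half-open (row, col) of each point; points must lie in the extent."""
        scalar = np.isscalar(x) and np.isscalar(y)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not np.all(self.contains(x, y)):
            raise ValueError("points outside the grid extent")
        col = np.floor((x - self.x0) / self.pixel_size).astype(np.int64)
        row = np.floor((y - self.y0) / self.pixel_size).astype(np.int64)
        # guard against floating roundoff exactly on the east/north edge
        np.clip(col, 0, self.n_cols - 1, out=col)
        np.clip(row, 0, self.n_rows - 1, out=row)
        if scalar:
            return int(row[0]), int(col[0])
        return row, col

    def same_geometry(self, other: "LandscapeGrid", atol: float = 1e-6) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x0 - other.x0) <= atol
            and abs(self.y0 - other.y0) <= atol
            and abs(self.pixel_size - other.pixel_size) <= atol
        )
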