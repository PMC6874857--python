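"""Regular raster grid specification on a projected planar CRS (meters).

Internal array convention: ``values[row, col]`` with row 0 the *southernmost*
row, so y increases with the row index.  File writers flip as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A rectangular grid of square pixels in projected coordinates.

    Parameters
    ----------
    origin_x, origin_y:
        Coordinates of the lower-left corner of the grid, in meters.
    pixel_size:
        Side length of a (square) pixel, in meters.  Default 500 m,
        i.e. ~0.25 km^2 per pixel.
    ncols, nrows:
        Grid dimensions.
    crs:
        Free-text note naming the projected CRS; no reprojection is done.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 500.0
    ncols: int = 100
    nrows: int = 100
    crs: str = field(default="local-projected-meters")

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one pixel per axis")

    @property
    def width(self) -> float:
        return self.ncols * self.pixel_size

    @property
    def height(self) -> float:
        return self.nrows * self.pixel_size

    @property
    def xmax(self) -> float:
        return self.origin_x + self.width

    @property
    def ymax(self) -> float:
        return self.origin_y + self.height

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.nrows) + 0.5) * self.pixel_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of pixel-center coordinates, shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.origin_x)
            & (x <= self.xmax)
            & (y >= self.origin_y)
            & (y <= self.ymax)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the pixel containing each point.

        Points exactly on the outer east/north edge snap to the last
        pixel (nearest-pixel rule); points outside the extent raise.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise ValueError(
                f"{bad.size} point(s) outside grid extent "
                f"[{self.origin_x}, {self.xmax}] x [{self.origin_y}, {self.ymax}]; "
                f"first offending index {bad[0]}"
            )
        col = np.clip(
            np.floor((x - self.origin_x) / self.pixel_size).astype(int),
            0,
            self.ncols - 1,
        )
        row = np.clip(
            np.floor((y - self.origin_y) / self.pixel_size).astype(int),
            0,
            self.nrows - 1,
        )
        return row, col
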