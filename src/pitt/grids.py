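"""Raster grid geometry shared by the SAR and high-resolution layers.

A grid is axis-aligned with square pixels of side ``L`` (map units, metres
for 10 m SAR or 2 m optical imagery).  Pixel ``(row, col)`` owns the
half-open footprint ``[x0 + col*L, x0 + (col+1)*L) x (y0 - (row+1)*L,
y0 - row*L]`` with the grid origin at the upper-left corner, matching the
usual north-up raster convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned square-pixel grid.

    Parameters
    ----------
    origin_x, origin_y : float
        Map coordinates of the upper-left corner of pixel (0, 0).
    pixel_side : float
        Side length L of each square pixel, in map units. Must be > 0.
    n_rows, n_cols : int
        Grid extent in pixels.
    """

    origin_x: float
    origin_y: float
    pixel_side: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.pixel_side <= 0:
            raise ValueError(f"pixel_side must be > 0, got {self.pixel_side}")
        if self.n_rows < 0 or self.n_cols < 0:
            raise ValueError("grid extent must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_center(self, row, col):
        """Map coordinates of pixel centers (vectorised over row/col)."""
        L = self.pixel_side
        x = self.origin_x + (np.asarray(col) + 0.5) * L
        y = self.origin_y - (np.asarray(row) + 0.5) * L
        return x, y

    def pixel_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) footprint of one pixel."""
        L = self.pixel_side
        minx = self.origin_x + col * L
        maxy = self.origin_y - row * L
        return (minx, maxy - L, minx + L, maxy)

    def window_for_bounds(self, minx, miny, maxx, maxy):
        """Row/col slice covering a bounding box, clipped to the grid."""
        L = self.pixel_side
        c0 = int(np.floor((minx - self.origin_x) / L))
        c1 = int(np.ceil((maxx - self.origin_x) / L))
        r0 = int(np.floor((self.origin_y - maxy) / L))
        r1 = int(np.ceil((self.origin_y - miny) / L))
        return (max(r0, 0), min(r1, self.n_rows), max(c0, 0), min(c1, self.n_cols))
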