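"""Parcel scale grading from maximum inscribed circles.

Irregular agricultural parcels are graded by how many whole, non-mixed SAR
pixels fit around their centre.  The grading statistic is the radius R of
the largest circle inscribed in the parcel polygon; a parcel reaches scale
level ``size_i`` when R clears the threshold

    R_ti = R_i + R_b

where ``R_i`` is the radius of the smallest circle centred on a pixel
center that fully contains the ``i`` lattice pixels nearest that center
(a single pixel for i=1, the cross of 5, the 3x3 block of 9, ...) and
``R_b`` is a buffer compensating for the circle centre generally not
being aligned with a pixel center (default: half a pixel diagonal).

Parcels at level >= 5 ("small") carry enough pure pixels for time-series
classification; parcels below ("micro", roughly < 0.1 ha on a 10 m grid)
are routed to the high-resolution texture branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import polylabel

from .grids import GridSpec

#: Canonical scale-level index sequence: pixel counts of centred lattice
#: neighbourhoods (none, single pixel, cross of 5, 3x3 block, next shell).
SIZE_LEVELS: tuple[int, ...] = (0, 1, 5, 9, 16)

#: Scale level at and above which a parcel counts as "small" (time-series
#: branch); below it the parcel is "micro" (texture branch).
SMALL_LEVEL: int = 5


class DegeneratePolygonError(ValueError):
    """Raised for polygons with zero area or fewer than 3 distinct vertices."""


@dataclass
class Parcel:
    """A delineated field polygon, the classification unit."""

    id: str
    polygon: Polygon
    truth_label: str | None = None
    scale_level: int | None = None
    inscribed_radius: float | None = None
    inscribed_center: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def branch(self) -> str | None:
        if self.scale_level is None:
            return None
        return "small" if self.scale_level >= SMALL_LEVEL else "micro"


def max_inscribed_circle(
    polygon: Polygon, tolerance: float | None = None
) -> tuple[Point, float]:
    """Largest circle fully inside ``polygon`` (holes respected).

    Uses iterative pole-of-inaccessibility refinement.  ``tolerance``
    defaults to 1e-3 times the smaller bounding-box side.

    Returns
    -------
    (center, radius) : (shapely Point, float)
    """
    if polygon is None or polygon.is_empty:
        raise DegeneratePolygonError("empty polygon")
    if not polygon.is_valid:
        raise DegeneratePolygonError(f"invalid polygon: {polygon.wkt[:80]}")
    if polygon.area <= 0:
        raise DegeneratePolygonError("polygon has zero area")
    if len(set(polygon.exterior.coords[:-1])) < 3:
        raise DegeneratePolygonError("fewer than 3 distinct vertices")
    if tolerance is None:
        minx, miny, maxx, maxy = polygon.bounds
        tolerance = 1e-3 * min(maxx - minx, maxy - miny)
        tolerance = max(tolerance, 1e-12)
    center = polylabel(polygon, tolerance=tolerance)
    radius = polygon.boundary.distance(center)
    return center, float(radius)


def standard_radius(i: int, grid: GridSpec | float) -> float:
    """Radius R_i of the smallest pixel-center-centred circle containing
    the ``i`` whole pixels nearest that center.

    ``grid`` may be a :class:`GridSpec` or the pixel side L directly.
    Only the canonical levels ``SIZE_LEVELS`` are accepted.
    """
    if i not in SIZE_LEVELS:
        raise ValueError(
            f"unsupported scale index {i}; supported indices: {list(SIZE_LEVELS)}"
        )
    L = grid.pixel_side if isinstance(grid, GridSpec) else float(grid)
    if L <= 0:
        raise ValueError("pixel side must be > 0")
    if i == 0:
        return 0.0
    return _containment_radii(i, L)[i - 1]


def _containment_radii(n: int, L: float) -> np.ndarray:
    """Sorted radii at which the circle centred on a pixel center fully
    contains its 1st, 2nd, ... n-th nearest whole pixel.

    A pixel at lattice offset (dx, dy) is contained once the radius
    reaches the distance to its farthest corner,
    ``L * hypot(|dx| + 1/2, |dy| + 1/2)``.  Ties are resolved by
    row-major enumeration order (which never affects the returned radii).
    """
    m = int(np.ceil(np.sqrt(n))) + 2
    offs = np.arange(-m, m + 1)
    dx, dy = np.meshgrid(offs, offs, indexing="xy")
    far = L * np.hypot(np.abs(dx) + 0.5, np.abs(dy) + 0.5)
    return np.sort(far.ravel(), kind="stable")[:n]


def radius_threshold(
    i: int,
    grid: GridSpec | float,
    buffer_mode: str = "half_diagonal",
    buffer_value: float | None = None,
) -> float:
    """Grading threshold R_ti = R_i + R_b.

    ``buffer_mode`` is ``"half_diagonal"`` (R_b = (sqrt 2 / 2) L, default)
    or ``"custom"`` with an explicit non-negative ``buffer_value``.
    """
    L = grid.pixel_side if isinstance(grid, GridSpec) else float(grid)
    if buffer_mode == "half_diagonal":
        rb = (np.sqrt(2.0) / 2.0) * L
    elif buffer_mode == "custom":
        if buffer_value is None:
            raise ValueError("buffer_mode='custom' requires buffer_value")
        if buffer_value < 0:
            raise ValueError(f"buffer must be non-negative, got {buffer_value}")
        rb = float(buffer_value)
    else:
        raise ValueError(f"unknown buffer_mode {buffer_mode!r}")
    return standard_radius(i, grid) + rb


def radius_thresholds_table(
    grid: GridSpec | float,
    levels: Sequence[int] = SIZE_LEVELS,
    buffer_mode: str = "half_diagonal",
    buffer_value: float | None = None,
) -> dict[int, float]:
    """Level -> R_ti table (strictly increasing in the level index)."""
    return {
        i: radius_threshold(i, grid, buffer_mode, buffer_value) for i in levels
    }


def grade_parcel(radius: float, thresholds: dict[int, float]) -> int:
    """Largest level i with R >= R_ti; level 0 if none is reached."""
    level = min(thresholds)
    for i, rt in sorted(thresholds.items()):
        if radius >= rt:
            level = i
    return level


def grade_and_partition(
    parcels: Iterable[Parcel],
    grid: GridSpec | float,
    buffer_mode: str = "half_diagonal",
    buffer_value: float | None = None,
) -> tuple[list[Parcel], list[str], list[str]]:
    """Assign scale levels and split parcel ids into (small, micro) lists.

    Computes the inscribed circle for any parcel that does not carry one
    yet.  The two id lists are disjoint and jointly cover the input.
    """
    thresholds = radius_thresholds_table(
        grid, buffer_mode=buffer_mode, buffer_value=buffer_value
    )
    parcels = list(parcels)
    small: list[str] = []
    micro: list[str] = []
    for p in parcels:
        if p.inscribed_radius is None:
            center, r = max_inscribed_circle(p.polygon)
            p.inscribed_radius = r
            p.inscribed_center = (center.x, center.y)
        p.scale_level = grade_parcel(p.inscribed_radius, thresholds)
        (small if p.scale_level >= SMALL_LEVEL else micro).append(p.id)
    return parcels, small, micro
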