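"""Parcel-level feature extraction from raster stacks.

Two feature streams feed the classifiers:

* per-parcel SAR backscatter time series, averaged over a selectable pixel
  set (all covered pixels, boundary pixels excluded, or the k pixels
  nearest the parcel centre) — the pixel-selection strategy controls how
  strongly boundary mixed pixels contaminate the series;
* square RGB texture chips cut from a single high-resolution optical
  image, centred on the parcel's inscribed-circle centre.

Pixel membership is decided by the pixel-center-in-polygon rule with an
unweighted mean, mirroring common zonal-statistics defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box

from .geometry import Parcel, max_inscribed_circle
from .grids import GridSpec

CHIP_SIDES = (8, 16, 32, 64, 96)
#: Chips smaller than this are upsampled (nearest neighbour) before use,
#: so a single backbone input size serves all micro-parcel chip scales.
CHIP_MIN_MODEL_SIDE = 32


@dataclass(frozen=True)
class RasterStack:
    """Co-registered per-date backscatter grids.

    ``data`` has shape (n_dates, n_rows, n_cols); ``dates`` are strictly
    increasing day-of-year integers; ``polarization`` is "VH" or "VV".
    """

    dates: tuple[int, ...]
    data: np.ndarray
    grid: GridSpec
    polarization: str = "VH"

    def __post_init__(self):
        if self.data.shape != (len(self.dates), self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.dates)} dates and grid {self.grid.shape}"
            )
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")


@dataclass
class TimeSeriesRecord:
    """One parcel's date-indexed backscatter vector."""

    parcel_id: str
    dates: tuple[int, ...]
    values: np.ndarray
    raw_mean_level: float
    raw_std: float = 0.0
    standardized: bool = False
    degenerate: bool = False
    method: str = "full"
    fallback: bool = False  # requested pixel set empty, fell back to full


@dataclass
class TextureChip:
    """Square RGB pixel block centred on a parcel."""

    parcel_id: str
    pixels: np.ndarray  # (side, side, 3)
    side: int
    resized_to: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def model_pixels(self) -> np.ndarray:
        """Chip at model input size (nearest-neighbour upsample if < 32)."""
        if self.side >= CHIP_MIN_MODEL_SIDE:
            return self.pixels
        factor = CHIP_MIN_MODEL_SIDE // self.side
        return np.repeat(np.repeat(self.pixels, factor, axis=0), factor, axis=1)


def classify_pixels(
    parcel: Parcel, grid: GridSpec
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], bool]:
    """Split the pixels covered by a parcel into interior and edge sets.

    A pixel is covered iff its center lies strictly inside the polygon;
    a covered pixel is interior iff its full square footprint lies in the
    polygon's interior (touching the boundary makes it an edge pixel).

    Returns (interior, edge, empty_warning) with (row, col) tuples in
    row-major order.
    """
    poly = parcel.polygon
    r0, r1, c0, c1 = grid.window_for_bounds(*poly.bounds)
    if r1 <= r0 or c1 <= c0:
        return [], [], True
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    cx, cy = grid.pixel_center(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(poly, cx, cy)
    interior: list[tuple[int, int]] = []
    edge: list[tuple[int, int]] = []
    for r, c in zip(rows.ravel()[inside], cols.ravel()[inside]):
        footprint = box(*grid.pixel_bounds(int(r), int(c)))
        if poly.contains_properly(footprint):
            interior.append((int(r), int(c)))
        else:
            edge.append((int(r), int(c)))
    return interior, edge, (not interior and not edge)


def _central_k_pixels(
    parcel: Parcel, grid: GridSpec, covered: list[tuple[int, int]], k: int
) -> list[tuple[int, int]]:
    """The k covered pixels nearest the inscribed-circle centre
    (row-major tie-break via stable sort on enumeration order)."""
    if parcel.inscribed_center is None:
        center, r = max_inscribed_circle(parcel.polygon)
        parcel.inscribed_center = (center.x, center.y)
        parcel.inscribed_radius = r
    px, py = parcel.inscribed_center
    rows = np.array([rc[0] for rc in covered])
    cols = np.array([rc[1] for rc in covered])
    cx, cy = grid.pixel_center(rows, cols)
    d2 = (cx - px) ** 2 + (cy - py) ** 2
    order = np.argsort(d2, kind="stable")
    return [covered[i] for i in order[:k]]


def extract_timeseries(
    parcel: Parcel,
    stack: RasterStack,
    method: str = "full",
    central_k: int = 9,
) -> TimeSeriesRecord:
    """Per-date mean backscatter over the selected pixel set.

    ``method`` is one of ``full`` (all covered pixels), ``edge_excluded``
    (interior pixels only) or ``central_k`` (the ``central_k`` covered
    pixels nearest the parcel centre).  If the requested set is empty the
    extraction falls back to ``full`` and flags the record.
    """
    if method not in ("full", "edge_excluded", "central_k"):
        raise ValueError(f"unknown extraction method {method!r}")
    interior, edge, empty = classify_pixels(parcel, stack.grid)
    covered = sorted(interior + edge)
    if empty or not covered:
        raise ValueError(f"parcel {parcel.id!r} covers no pixel centers")
    fallback = False
    if method == "edge_excluded":
        selected = interior
        if not selected:
            selected, fallback = covered, True
    elif method == "central_k":
        selected = _central_k_pixels(parcel, stack.grid, covered, central_k)
        if not selected:
            selected, fallback = covered, True
    else:
        selected = covered
    rows = [rc[0] for rc in selected]
    cols = [rc[1] for rc in selected]
    values = stack.data[:, rows, cols].mean(axis=1)
    return TimeSeriesRecord(
        parcel_id=parcel.id,
        dates=stack.dates,
        values=values.astype(float),
        raw_mean_level=float(values.mean()),
        raw_std=float(values.std()),
        method=method,
        fallback=fallback,
    )


def mean_standardize(
    record: TimeSeriesRecord, mode: str = "zscore", eps: float = 1e-12
) -> TimeSeriesRecord:
    """Standardize a series for scale-consistent shape comparison.

    ``mode='zscore'`` (default) gives zero mean and unit variance, the
    preprocessing the shape-based clustering distance assumes;
    ``mode='center'`` only removes the mean.  The raw mean level is
    preserved on the record so amplitude conflicts between similar shapes
    can still be detected downstream.  Idempotent on already-standardized
    input; a zero-variance series maps to the zero vector with
    ``degenerate=True``.
    """
    if mode not in ("zscore", "center"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    v = np.asarray(record.values, dtype=float)
    centered = v - v.mean()
    sd = v.std()
    degenerate = sd < eps
    if mode == "zscore":
        out = np.zeros_like(v) if degenerate else centered / sd
    else:
        out = centered
    return TimeSeriesRecord(
        parcel_id=record.parcel_id,
        dates=record.dates,
        values=out,
        raw_mean_level=record.raw_mean_level,
        raw_std=record.raw_std if record.standardized else float(sd),
        standardized=True,
        degenerate=degenerate or record.degenerate,
        method=record.method,
        fallback=record.fallback,
    )


def zscore(values: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Row-wise z-normalization of a (n, T) array (zero rows stay zero)."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    centered = v - v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    out = np.where(sd < eps, 0.0, centered / np.where(sd < eps, 1.0, sd))
    return out.reshape(np.shape(values))


def extract_chip(
    parcel: Parcel,
    image: np.ndarray,
    grid: GridSpec,
    side: int,
    masked: bool = False,
) -> TextureChip:
    """Cut a side x side RGB window centred on the parcel centre.

    The window is clipped at image borders and zero-padded back to the
    full side.  With ``masked=True`` pixels outside the parcel polygon
    are zeroed (default keeps the raw square window).
    """
    if side not in CHIP_SIDES:
        raise ValueError(f"side must be one of {CHIP_SIDES}, got {side}")
    if parcel.inscribed_center is None:
        center, r = max_inscribed_circle(parcel.polygon)
        parcel.inscribed_center = (center.x, center.y)
        parcel.inscribed_radius = r
    px, py = parcel.inscribed_center
    L = grid.pixel_side
    col_c = (px - grid.origin_x) / L
    row_c = (grid.origin_y - py) / L
    if not (0 <= row_c <= grid.n_rows and 0 <= col_c <= grid.n_cols):
        raise ValueError(f"parcel {parcel.id!r} centre lies outside the image")
    r0 = int(np.floor(row_c)) - side // 2
    c0 = int(np.floor(col_c)) - side // 2
    chip = np.zeros((side, side, image.shape[2]), dtype=image.dtype)
    rs, re = max(r0, 0), min(r0 + side, image.shape[0])
    cs, ce = max(c0, 0), min(c0 + side, image.shape[1])
    if re > rs and ce > cs:
        chip[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    if masked:
        rows, cols = np.meshgrid(
            np.arange(r0, r0 + side), np.arange(c0, c0 + side), indexing="ij"
        )
        cx, cy = grid.pixel_center(rows.ravel(), cols.ravel())
        inside = shapely.contains_xy(parcel.polygon, cx, cy).reshape(side, side)
        chip = chip * inside[:, :, None]
    resized = CHIP_MIN_MODEL_SIDE if side < CHIP_MIN_MODEL_SIDE else None
    return TextureChip(parcel_id=parcel.id, pixels=chip, side=side, resized_to=resized)
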