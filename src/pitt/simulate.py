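"""Synthetic smallholder scenes for exercising every pipeline stage.

A scene emulates a winter-crop season in a fragmented agricultural
landscape observed by a medium-resolution SAR sensor and one
high-resolution optical image:

* irregular parcel polygons produced by jittered-Voronoi mosaics,
  scaled to hit requested scale-level strata (from micro parcels under
  0.1 ha up to multi-pixel small parcels);
* a 10-date VH backscatter stack (early January to late May): the
  winter-wheat template decreases gradually through the season, the
  winter-rapeseed template rises to a mid-April peak before declining
  sharply, and a third near-flat class stands in for bare land and
  grassland.  Every pixel's clean value is the area-weighted blend of
  the curves of all parcels overlapping its footprint — the boundary
  mixed-pixel mechanism — plus i.i.d. Gaussian backscatter noise;
* one RGB image in which each class carries an oriented periodic
  texture (stripe period / orientation / contrast per class).

Within-class variability is a per-parcel level offset plus a smooth
curve perturbation; wheat is given more within-class spread than
rapeseed so the two crops' group statistics separate realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import Polygon, box
from scipy.spatial import Voronoi

from .features import RasterStack
from .geometry import (
    Parcel,
    grade_and_partition,
    max_inscribed_circle,
    radius_thresholds_table,
)
from .grids import GridSpec
from .ki import PhenologyReference

#: Acquisition days-of-year spanning Jan 8 - May 20 (10 dates).
DEFAULT_DATES = (8, 23, 38, 52, 67, 82, 96, 111, 126, 140)

#: Piecewise-linear VH template control points per class, (DOY, dB).
CURVE_TEMPLATES = {
    "rape": ((8, -17.0), (38, -16.0), (67, -14.5), (96, -11.5), (105, -11.0),
             (126, -15.0), (140, -16.5)),
    "wheat": ((8, -13.5), (38, -15.0), (67, -16.5), (96, -17.5), (126, -18.5),
              (140, -19.0)),
    # grass/bare land: gentle green-up through spring, ~2 dB rise
    "other": ((8, -13.5), (38, -13.8), (67, -13.0), (96, -12.2), (126, -11.8),
              (140, -11.6)),
}

#: Background (non-parcel) VH level, bare-soil-like.
BACKGROUND_LEVEL = -12.0

#: Oriented texture parameters per class:
#: (stripe period in map units, orientation degrees, contrast, RGB base).
TEXTURE_PARAMS = {
    "rape": (8.0, 0.0, 0.25, (0.55, 0.50, 0.20)),
    "wheat": (8.0, 90.0, 0.25, (0.25, 0.45, 0.25)),
    "other": (12.0, 45.0, 0.05, (0.50, 0.45, 0.40)),
}


@dataclass(frozen=True)
class SceneConfig:
    seed: int = 7
    pixel_side: float = 10.0
    hires_side: float = 2.0
    dates: tuple[int, ...] = DEFAULT_DATES
    classes: tuple[str, ...] = ("rape", "wheat", "other")
    #: requested scale level -> parcels per class at that level
    parcels_per_level_per_class: dict = field(
        default_factory=lambda: {0: 50, 1: 50, 5: 50, 9: 50}
    )
    #: per-pixel per-date additive Gaussian backscatter noise (dB)
    noise_sigma: float = 1.0
    #: per-parcel level-offset jitter sd (dB); wheat spreads the most
    offset_sd: dict = field(
        default_factory=lambda: {"rape": 0.3, "wheat": 0.6, "other": 0.5}
    )
    #: per-parcel smooth curve perturbation sd (dB)
    shape_sd: dict = field(
        default_factory=lambda: {"rape": 0.6, "wheat": 1.0, "other": 0.8}
    )
    texture_noise: float = 0.03
    multiplicative_noise: bool = False  # speckle-like alternative

    def __post_init__(self):
        if any(s < 0 for s in (self.noise_sigma, self.texture_noise)):
            raise ValueError("noise levels must be non-negative")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")


@dataclass
class Scene:
    config: SceneConfig
    parcels: list[Parcel]
    small_ids: list[str]
    micro_ids: list[str]
    truth: pd.DataFrame  # parcel_id, class, requested_level, scale_level
    clean_curves: dict[str, np.ndarray]
    grid: GridSpec
    stack: RasterStack | None = None
    hires: np.ndarray | None = None
    hires_grid: GridSpec | None = None
    references: PhenologyReference | None = None

    def parcel(self, pid: str) -> Parcel:
        return next(p for p in self.parcels if p.id == pid)


def class_template(cls: str, dates) -> np.ndarray:
    pts = np.asarray(CURVE_TEMPLATES[cls], dtype=float)
    return np.interp(np.asarray(dates, dtype=float), pts[:, 0], pts[:, 1])


def make_references(dates) -> PhenologyReference:
    """Typical-sample phenology curves: the clean class templates."""
    return PhenologyReference(
        dates=np.asarray(dates, dtype=float),
        curves={c: class_template(c, dates) for c in CURVE_TEMPLATES},
    )


# -------------------------------------------------------------- parcels

def _level_radius_bands(L: float) -> dict[int, tuple[float, float]]:
    """Target inscribed-radius interval per requested scale level."""
    rt = radius_thresholds_table(L)
    # level-0 lower bound 0.72 L: an inscribed circle of that radius is
    # guaranteed to contain a pixel center, so every parcel is observable
    return {
        0: (0.72 * L, 0.95 * rt[1]),
        1: (1.02 * rt[1], 0.95 * rt[5]),
        5: (1.02 * rt[5], 0.95 * rt[9]),
        9: (1.02 * rt[9], 0.95 * rt[16]),
    }


def _voronoi_band(
    n: int, cell: float, y0: float, rng: np.random.Generator
) -> tuple[list[Polygon], float]:
    """~n jittered-Voronoi cells in a horizontal band starting at y0.

    Returns the interior cell polygons (clipped to the band) and the
    band height.  A guard ring of extra seed points keeps interior
    cells bounded.
    """
    ncols = int(np.ceil(np.sqrt(n * 1.6)))
    nrows = int(np.ceil(n / ncols))
    jitter = 0.12 * cell
    pts = []
    interior = []
    for r in range(-1, nrows + 1):
        for c in range(-1, ncols + 1):
            x = (c + 0.5) * cell + rng.uniform(-jitter, jitter)
            y = y0 + (r + 0.5) * cell + rng.uniform(-jitter, jitter)
            pts.append((x, y))
            if 0 <= r < nrows and 0 <= c < ncols:
                interior.append(len(pts) - 1)
    vor = Voronoi(np.asarray(pts))
    band = box(0, y0, ncols * cell, y0 + nrows * cell)
    polys = []
    for idx in interior:
        region = vor.regions[vor.point_region[idx]]
        if -1 in region or not region:
            continue
        poly = Polygon(vor.vertices[region]).intersection(band)
        if poly.geom_type == "Polygon" and poly.area > 0:
            polys.append(poly)
        if len(polys) == n:
            break
    return polys, nrows * cell


def simulate_parcels(config: SceneConfig) -> tuple[list[Parcel], pd.DataFrame]:
    """Parcel mosaic hitting the requested size strata.

    Deterministic given the config seed.  Returns parcels (with truth
    labels attached) and the truth table.
    """
    rng = np.random.default_rng(config.seed)
    L = config.pixel_side
    bands = _level_radius_bands(L)
    unsupported = set(config.parcels_per_level_per_class) - set(bands)
    if unsupported:
        raise ValueError(f"unsupported requested levels {sorted(unsupported)}")
    parcels: list[Parcel] = []
    rows = []
    y0 = L  # one-pixel margin
    counter = 0
    for level in sorted(config.parcels_per_level_per_class):
        per_class = config.parcels_per_level_per_class[level]
        n = per_class * len(config.classes)
        if n == 0:
            continue
        rmin, rmax = bands[level]
        cell = 2.6 * rmax
        polys, height = _voronoi_band(n, cell, y0, rng)
        if len(polys) < n:
            raise ValueError(
                f"could not place {n} parcels at level {level} (got {len(polys)})"
            )
        labels = rng.permutation(np.repeat(config.classes, per_class))
        for poly, cls in zip(polys, labels):
            center, r0 = max_inscribed_circle(poly)
            target = rng.uniform(rmin, rmax)
            target = min(target, 0.97 * r0)
            factor = target / r0
            scaled = affinity.scale(poly, xfact=factor, yfact=factor, origin=center)
            pid = f"P{counter:04d}"
            counter += 1
            parcels.append(Parcel(id=pid, polygon=scaled, truth_label=str(cls)))
            rows.append({"parcel_id": pid, "class": str(cls), "requested_level": level})
        y0 += height + L
    truth = pd.DataFrame(rows)
    return parcels, truth


# ---------------------------------------------------------------- rasters

def _parcel_curves(
    truth: pd.DataFrame,
    parcels: list[Parcel],
    config: SceneConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-parcel clean curve: class template + offset + smooth jitter.

    The jitter scale is multiplied by the parcel's boundary-affected
    area fraction (perimeter * pixel side / area, clipped): small
    fields deviate more from their crop's typical curve because a
    larger share of their area sits in the boundary zone.
    """
    dates = np.asarray(config.dates, dtype=float)
    anchors = np.linspace(dates[0], dates[-1], 4)
    polys = {p.id: p.polygon for p in parcels}
    L = config.pixel_side
    curves = {}
    for pid, cls in zip(truth["parcel_id"], truth["class"]):
        base = class_template(cls, dates)
        poly = polys[pid]
        boundary_factor = float(np.clip(poly.length * L / poly.area, 0.3, 1.5))
        offset = rng.normal(0.0, boundary_factor * config.offset_sd[cls])
        knots = rng.normal(
            0.0, boundary_factor * config.shape_sd[cls], size=anchors.size
        )
        curves[pid] = base + offset + np.interp(dates, anchors, knots)
    return curves


def simulate_sar_stack(
    parcels: list[Parcel],
    clean_curves: dict[str, np.ndarray],
    config: SceneConfig,
    grid: GridSpec,
    rng: np.random.Generator | None = None,
) -> RasterStack:
    """Mixed-pixel SAR stack.

    Each pixel's clean value is the footprint-area-weighted blend of the
    curves of all overlapping parcels (plus the background curve for
    uncovered area); noise is then added per pixel per date.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_dates = len(config.dates)
    L = grid.pixel_side
    weighted = np.zeros((n_dates, grid.n_rows, grid.n_cols))
    weight = np.zeros((grid.n_rows, grid.n_cols))
    for p in parcels:
        curve = clean_curves[p.id]
        r0, r1, c0, c1 = grid.window_for_bounds(*p.polygon.bounds)
        for r in range(r0, r1):
            for c in range(c0, c1):
                frac = p.polygon.intersection(box(*grid.pixel_bounds(r, c))).area / L**2
                if frac > 0:
                    weighted[:, r, c] += frac * curve
                    weight[r, c] += frac
    background = np.full(n_dates, BACKGROUND_LEVEL)
    clean = weighted + (1.0 - np.clip(weight, 0, 1))[None] * background[:, None, None]
    if config.noise_sigma > 0:
        noise = rng.normal(0.0, config.noise_sigma, size=clean.shape)
        if config.multiplicative_noise:
            data = clean * (1.0 + noise / np.abs(clean).mean())
        else:
            data = clean + noise
    else:
        data = clean
    return RasterStack(dates=tuple(config.dates), data=data, grid=grid)


def mixed_pixel_fraction(parcel: Parcel, grid: GridSpec) -> float:
    """Fraction of a parcel's covered pixels whose footprint crosses the
    parcel boundary (boundary mixed pixels)."""
    from .features import classify_pixels

    interior, edge, empty = classify_pixels(parcel, grid)
    total = len(interior) + len(edge)
    return float(len(edge) / total) if total else 1.0


def simulate_texture_image(
    parcels: list[Parcel],
    truth: pd.DataFrame,
    config: SceneConfig,
    hires_grid: GridSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """High-resolution RGB image with class-distinct oriented textures."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    H, W = hires_grid.n_rows, hires_grid.n_cols
    img = np.full((H, W, 3), 0.35)
    cls_of = dict(zip(truth["parcel_id"], truth["class"]))
    for p in parcels:
        period, theta_deg, contrast, base = TEXTURE_PARAMS[cls_of[p.id]]
        phase = rng.uniform(0, 2 * np.pi)
        r0, r1, c0, c1 = hires_grid.window_for_bounds(*p.polygon.bounds)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        x, y = hires_grid.pixel_center(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(p.polygon, x, y)
        if not inside.any():
            continue
        theta = np.deg2rad(theta_deg)
        stripe = np.sin(2 * np.pi * (x * np.cos(theta) + y * np.sin(theta)) / period + phase)
        rows_in = rr.ravel()[inside]
        cols_in = cc.ravel()[inside]
        for b in range(3):
            img[rows_in, cols_in, b] = base[b] + contrast * stripe[inside]
    if config.texture_noise > 0:
        img = img + rng.normal(0.0, config.texture_noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ----------------------------------------------------------------- scenes

def build_scene(
    config: SceneConfig, with_texture: bool = True, with_stack: bool = True
) -> Scene:
    """Generate a full scene bundle from a config (deterministic)."""
    parcels, truth = simulate_parcels(config)
    L = config.pixel_side
    maxx = max(p.polygon.bounds[2] for p in parcels) + L
    maxy = max(p.polygon.bounds[3] for p in parcels) + L
    grid = GridSpec(
        origin_x=0.0,
        origin_y=float(np.ceil(maxy / L) * L),
        pixel_side=L,
        n_rows=int(np.ceil(maxy / L)),
        n_cols=int(np.ceil(maxx / L)),
    )
    parcels, small_ids, micro_ids = grade_and_partition(parcels, grid)
    levels = {p.id: p.scale_level for p in parcels}
    truth = truth.assign(scale_level=[levels[i] for i in truth["parcel_id"]])
    rng = np.random.default_rng(config.seed + 1)
    curves = _parcel_curves(truth, parcels, config, rng)
    scene = Scene(
        config=config,
        parcels=parcels,
        small_ids=small_ids,
        micro_ids=micro_ids,
        truth=truth,
        clean_curves=curves,
        grid=grid,
        references=make_references(config.dates),
    )
    if with_stack:
        scene.stack = simulate_sar_stack(parcels, curves, config, grid, rng)
    if with_texture:
        hl = config.hires_side
        scene.hires_grid = GridSpec(
            origin_x=0.0,
            origin_y=grid.origin_y,
            pixel_side=hl,
            n_rows=int(round(grid.n_rows * L / hl)),
            n_cols=int(round(grid.n_cols * L / hl)),
        )
        scene.hires = simulate_texture_image(
            parcels, truth, config, scene.hires_grid,
            np.random.default_rng(config.seed + 2),
        )
    return scene


def standard_scene(seed: int = 7, with_texture: bool = True) -> Scene:
    """The fixed benchmark scene: 600 parcels, 3 classes, 50 parcels per
    class at each requested level in {0, 1, 5, 9}."""
    return build_scene(SceneConfig(seed=seed), with_texture=with_texture)


def ptr_scene(seed: int = 7, per_group: int = 100) -> Scene:
    """Representativeness benchmark: the two winter crops only, with
    ``per_group`` parcels per (size level, crop) stratum; no texture
    image (the statistic only needs the SAR series)."""
    config = SceneConfig(
        seed=seed,
        classes=("rape", "wheat"),
        parcels_per_level_per_class={0: per_group, 1: per_group, 5: per_group, 9: per_group},
    )
    return build_scene(config, with_texture=False)


def small_scene(seed: int = 0, per_group: int = 12, with_texture: bool = True) -> Scene:
    """Reduced scene for fast tests (same structure, fewer parcels)."""
    config = SceneConfig(
        seed=seed,
        parcels_per_level_per_class={0: per_group, 1: per_group, 5: per_group, 9: per_group},
    )
    return build_scene(config, with_texture=with_texture)
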