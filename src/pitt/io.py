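"""File formats: GeoJSON parcels, TIFF rasters with sidecar metadata,
CSV tables for series, probabilities, pseudolabels and references.

All inputs are assumed to share one planar CRS; no reprojection is
performed.  Raster stacks are stored as one single-band TIFF per date
plus ``dates.csv`` (columns date, filename) and ``grid.json`` carrying
the georeferencing (origin, pixel side, extent).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .features import RasterStack, TextureChip, TimeSeriesRecord
from .geometry import Parcel
from .grids import GridSpec

# ------------------------------------------------------------- parcels


def parcels_to_geojson(parcels: list[Parcel], path: str | Path) -> None:
    features = []
    for p in parcels:
        props = {"id": p.id}
        if p.truth_label is not None:
            props["label"] = p.truth_label
        if p.scale_level is not None:
            props["scale_level"] = p.scale_level
            props["branch"] = p.branch
        if p.inscribed_radius is not None:
            props["inscribed_radius"] = round(p.inscribed_radius, 6)
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(p.polygon)}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def parcels_from_geojson(path: str | Path) -> list[Parcel]:
    doc = json.loads(Path(path).read_text())
    parcels = []
    for i, feat in enumerate(doc["features"]):
        props = feat.get("properties") or {}
        p = Parcel(
            id=str(props.get("id", i)),
            polygon=shape(feat["geometry"]),
            truth_label=props.get("label"),
            scale_level=props.get("scale_level"),
            inscribed_radius=props.get("inscribed_radius"),
        )
        parcels.append(p)
    return parcels


# -------------------------------------------------------------- rasters


def _grid_to_dict(grid: GridSpec) -> dict:
    return {
        "origin_x": grid.origin_x,
        "origin_y": grid.origin_y,
        "pixel_side": grid.pixel_side,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
    }


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(**d)


def stack_to_dir(stack: RasterStack, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, date in enumerate(stack.dates):
        fname = f"vh_doy{date:03d}.tif"
        tifffile.imwrite(out / fname, stack.data[i].astype(np.float32))
        rows.append({"date": date, "filename": fname})
    pd.DataFrame(rows).to_csv(out / "dates.csv", index=False)
    (out / "grid.json").write_text(
        json.dumps({**_grid_to_dict(stack.grid), "polarization": stack.polarization})
    )


def stack_from_dir(in_dir: str | Path) -> RasterStack:
    src = Path(in_dir)
    meta = json.loads((src / "grid.json").read_text())
    pol = meta.pop("polarization", "VH")
    grid = _grid_from_dict(meta)
    dates_df = pd.read_csv(src / "dates.csv").sort_values("date")
    data = np.stack(
        [tifffile.imread(src / f).astype(float) for f in dates_df["filename"]]
    )
    return RasterStack(
        dates=tuple(int(d) for d in dates_df["date"]), data=data, grid=grid,
        polarization=pol,
    )


def image_write(image: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    path = Path(path)
    photometric = "rgb" if image.ndim == 3 and image.shape[2] == 3 else "minisblack"
    tifffile.imwrite(path, image.astype(np.float32), photometric=photometric)
    path.with_suffix(".grid.json").write_text(json.dumps(_grid_to_dict(grid)))


def image_read(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    path = Path(path)
    image = tifffile.imread(path).astype(float)
    grid = _grid_from_dict(json.loads(path.with_suffix(".grid.json").read_text()))
    return image, grid


# --------------------------------------------------------------- tables


def records_to_frame(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for d, v in zip(r.dates, r.values):
            rows.append(
                {
                    "parcel_id": r.parcel_id,
                    "date": int(d),
                    "value": float(v),
                    "method": r.method,
                }
            )
    return pd.DataFrame(rows, columns=["parcel_id", "date", "value", "method"])


def records_from_frame(df: pd.DataFrame) -> list[TimeSeriesRecord]:
    records = []
    for pid, sub in df.groupby("parcel_id", sort=True):
        sub = sub.sort_values("date")
        values = sub["value"].to_numpy(dtype=float)
        records.append(
            TimeSeriesRecord(
                parcel_id=str(pid),
                dates=tuple(int(d) for d in sub["date"]),
                values=values,
                raw_mean_level=float(values.mean()),
                raw_std=float(values.std()),
                method=str(sub["method"].iloc[0]) if "method" in sub else "full",
            )
        )
    return records


def chips_to_dir(chips: list[TextureChip], out_dir: str | Path) -> None:
    """One .npy block per chip (float RGB) plus an index CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in chips:
        fname = f"{c.parcel_id}.npy"
        np.save(out / fname, c.pixels.astype(np.float32))
        rows.append(
            {"parcel_id": c.parcel_id, "filename": fname, "side": c.side,
             "resized_to": c.resized_to if c.resized_to else ""}
        )
    pd.DataFrame(rows).to_csv(out / "index.csv", index=False)


def chips_from_dir(in_dir: str | Path) -> list[TextureChip]:
    src = Path(in_dir)
    index = pd.read_csv(src / "index.csv", keep_default_na=False)
    chips = []
    for _, row in index.iterrows():
        pixels = np.load(src / row["filename"]).astype(float)
        chips.append(
            TextureChip(
                parcel_id=str(row["parcel_id"]),
                pixels=pixels,
                side=int(row["side"]),
                resized_to=int(row["resized_to"]) if str(row["resized_to"]) else None,
            )
        )
    return chips


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer (fixed float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
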