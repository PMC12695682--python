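"""File-format helpers: calibrated slides (TIFF/PNG + metadata sidecar),
fascicle ROIs as GeoJSON polygons in pixel coordinates, and CSV tables with
a provenance header."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .render import FascicleROI, SlideImage

__all__ = [
    "save_slide",
    "load_slide",
    "rois_to_geojson",
    "rois_from_geojson",
    "write_table",
    "read_table",
]


def save_slide(slide: SlideImage, path: str | Path) -> None:
    """Write a slide as TIFF (.tif/.tiff) or PNG plus a ``.meta.yaml`` sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, slide.pixels)
    else:
        Image.fromarray(slide.pixels).save(path)
    meta = {
        "microns_per_pixel": slide.microns_per_pixel,
        "orientation": slide.orientation,
        "stain": slide.stain,
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def load_slide(path: str | Path) -> SlideImage:
    """Load a slide written by :func:`save_slide`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    return SlideImage(pixels=pixels, **meta)


def rois_to_geojson(rois: list[FascicleROI], path: str | Path) -> None:
    """Write ROIs as a GeoJSON FeatureCollection (pixel coordinates)."""
    features = [
        {
            "type": "Feature",
            "properties": {"label": r.label, "usable": r.usable},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(map(float, p)) for p in r.polygon] + [list(map(float, r.polygon[0]))]],
            },
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def rois_from_geojson(path: str | Path) -> list[FascicleROI]:
    data = json.loads(Path(path).read_text())
    rois = []
    for feat in data["features"]:
        ring = feat["geometry"]["coordinates"][0]
        if ring[0] == ring[-1]:
            ring = ring[:-1]
        props = feat.get("properties", {})
        rois.append(
            FascicleROI(
                polygon=[tuple(p) for p in ring],
                label=props.get("label", "roi"),
                usable=bool(props.get("usable", True)),
            )
        )
    return rois


def write_table(df: pd.DataFrame, path: str | Path, header: list[str] | None = None) -> None:
    """Write a CSV with ``#``-prefixed provenance header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
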