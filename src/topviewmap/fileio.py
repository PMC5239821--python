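"""Reading and writing the pipeline's on-disk formats.

Images are 8/16-bit grayscale TIFF or PNG.  Delineations are one JSON file
per slice with all coordinates in continuous pixel units (the loader converts
to mm with ``pixel_size_mm``).  Slice metadata is a TSV with columns
condition, animal, filename, bregma_mm.  Maps are persisted as a TSV grid
(first column bregma_mm, remaining columns one per lateral sample) plus a
JSON sidecar with the full grid geometry; reject contours and masks travel
as GeoJSON in map mm coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .maps import ReferenceMap
from .slices import Line, SliceDelineation, SliceMetadata

__all__ = [
    "read_image",
    "write_image",
    "read_delineation",
    "write_delineation",
    "read_metadata",
    "write_metadata",
    "write_map_tsv",
    "read_map_tsv",
    "write_reference_map",
    "read_reference_map",
    "write_contours_geojson",
    "read_mask_geojson",
]

METADATA_COLUMNS = ["condition", "animal", "filename", "bregma_mm"]


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse an accidental RGB to luminance
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D grayscale image")
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


# ---------------------------------------------------------------------------
# delineation JSON (pixel coordinates on disk, mm in memory)


def write_delineation(path: str | Path, d: SliceDelineation) -> None:
    ps = d.pixel_size
    line = d.reference_line
    # two points on the line, for a human-readable representation
    if abs(line.b) >= abs(line.a):
        xs = np.array([0.0, 1.0])
        pts = np.column_stack([xs, -(line.a * xs + line.c) / line.b])
    else:
        ys = np.array([0.0, 1.0])
        pts = np.column_stack([-(line.b * ys + line.c) / line.a, ys])
    payload = {
        "pixel_size_mm": ps,
        "top_edge": (d.top_edge / ps).tolist(),
        "bottom_edge": (d.bottom_edge / ps).tolist(),
        "landmarks": (d.landmarks / ps).tolist(),
        "background_box": [v / ps for v in d.background_box],
        "reference_line": (pts / ps).tolist(),
        "signal_polarity": d.signal_polarity,
    }
    Path(path).write_text(json.dumps(payload))


def read_delineation(path: str | Path) -> SliceDelineation:
    payload = json.loads(Path(path).read_text())
    ps = float(payload["pixel_size_mm"])
    p1, p2 = [np.asarray(p, dtype=float) * ps for p in payload["reference_line"]]
    return SliceDelineation(
        top_edge=np.asarray(payload["top_edge"], dtype=float) * ps,
        bottom_edge=np.asarray(payload["bottom_edge"], dtype=float) * ps,
        landmarks=np.asarray(payload["landmarks"], dtype=float).reshape(-1, 2) * ps,
        background_box=tuple(float(v) * ps for v in payload["background_box"]),
        reference_line=Line.from_points(p1, p2),
        pixel_size=ps,
        signal_polarity=payload.get("signal_polarity", "dark_signal"),
    )


# ---------------------------------------------------------------------------
# metadata TSV


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata is missing columns: {missing}")
    if df.empty:
        raise ValidationError("no slices: metadata table is empty")
    return df


def write_metadata(path: str | Path, records: list[dict]) -> None:
    pd.DataFrame(records, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def metadata_row_to_slice(row) -> SliceMetadata:
    return SliceMetadata(
        condition=str(row["condition"]),
        animal=str(row["animal"]),
        filename=str(row["filename"]),
        bregma=float(row["bregma_mm"]),
    )


# ---------------------------------------------------------------------------
# map rasters


def write_map_tsv(path: str | Path, raster: np.ndarray, bregma_grid: np.ndarray,
                  lateral_labels: np.ndarray) -> None:
    df = pd.DataFrame(raster, columns=[f"{v:.4f}" for v in lateral_labels])
    df.insert(0, "bregma_mm", bregma_grid)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_map_tsv(path: str | Path) -> tuple:
    df = pd.read_csv(path, sep="\t")
    bregma = df.pop("bregma_mm").to_numpy()
    lateral = np.array([float(c) for c in df.columns])
    return df.to_numpy(dtype=float), bregma, lateral


def write_reference_map(path: str | Path, ref: ReferenceMap) -> None:
    payload = {
        "bregma_grid_mm": ref.bregma_grid.tolist(),
        "positions_mm": ref.positions.tolist(),
        "landmarks_mm": ref.landmarks.tolist(),
        "interval_mm": ref.interval,
    }
    Path(path).write_text(json.dumps(payload))


def read_reference_map(path: str | Path) -> ReferenceMap:
    payload = json.loads(Path(path).read_text())
    return ReferenceMap(
        bregma_grid=np.asarray(payload["bregma_grid_mm"], dtype=float),
        positions=np.asarray(payload["positions_mm"], dtype=float),
        landmarks=np.asarray(payload["landmarks_mm"], dtype=float),
        interval=float(payload["interval_mm"]),
    )


# ---------------------------------------------------------------------------
# GeoJSON contours / masks


def write_contours_geojson(path: str | Path, contours: dict) -> None:
    """Persist reject-boundary contours (row/col vertex lists) as GeoJSON."""
    features = []
    for level, curves in contours.items():
        for curve in curves:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"level": level},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(c), float(r)] for r, c in curve],
                    },
                }
            )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_mask_geojson(path: str | Path) -> dict:
    """Load mask polygons as {label: shapely Polygon} in map mm coordinates."""
    from shapely.geometry import shape

    payload = json.loads(Path(path).read_text())
    polygons = {}
    for i, feat in enumerate(payload.get("features", [])):
        label = int(feat.get("properties", {}).get("label", i + 1))
        polygons[label] = shape(feat["geometry"])
    return polygons
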