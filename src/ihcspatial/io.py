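"""Reading and writing the pipeline's file formats.

Images: 8-bit RGB TIFF or PNG.  Point tables: CSV with columns
``sample_id,field_id,x,y,label,window_width,window_height``.  Results:
JSON records with sorted keys so identical runs are byte-identical.
Cohort manifests: JSON lists of per-field entries.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .geometry import PointPattern, Window
from .stains import RasterField

POINT_COLUMNS = ["sample_id", "field_id", "x", "y", "label",
                 "window_width", "window_height"]


def read_image(path: str | Path, field_id: str | None = None) -> RasterField:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return RasterField(np.asarray(pixels), field_id=field_id or path.stem)


def write_image(field: RasterField, path: str | Path) -> None:
    path = Path(path)
    pixels = np.clip(np.round(field.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_pattern_csv(pattern: PointPattern, path: str | Path,
                      sample_id: str = "", label: str = "") -> None:
    df = pd.DataFrame({
        "sample_id": sample_id,
        "field_id": pattern.field_id,
        "x": pattern.x,
        "y": pattern.y,
        "label": label or pattern.marker,
        "window_width": pattern.window.width,
        "window_height": pattern.window.height,
    }, columns=POINT_COLUMNS)
    df.to_csv(path, index=False)


def read_pattern_csv(path: str | Path) -> PointPattern:
    df = pd.read_csv(path)
    missing = {"x", "y", "window_width", "window_height"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: point CSV missing columns {sorted(missing)}")
    window = Window(float(df["window_width"].iloc[0]) if len(df) else 1.0,
                    float(df["window_height"].iloc[0]) if len(df) else 1.0)
    field_id = str(df["field_id"].iloc[0]) if "field_id" in df.columns and len(df) else Path(path).stem
    marker = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else "synthetic"
    return PointPattern(df["x"].to_numpy(float), df["y"].to_numpy(float),
                        window, field_id=field_id, marker=marker)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, sort_keys=True, indent=1,
                                     default=_jsonable) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(entries: list[dict], path: str | Path) -> None:
    write_json({"fields": entries}, path)


def read_manifest(path: str | Path) -> list[dict]:
    record = read_json(path)
    if "fields" not in record:
        raise ValueError(f"{path}: manifest must contain a 'fields' list")
    return record["fields"]
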