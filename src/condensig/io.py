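"""File I/O: TIFF images, label masks, tidy CSV tables, JSON/YAML sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ktr_pulses import TRACE_COLUMNS
from .puncta import LabeledImage


def write_intensity_tiff(path, intensity: np.ndarray) -> None:
    """Write an intensity grid as 16-bit single-channel TIFF (values clipped
    and rounded to the uint16 range)."""
    arr = np.clip(np.rint(intensity), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def write_labels_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.int32))


def write_labeled_image(img: LabeledImage, intensity_path, labels_path) -> None:
    write_intensity_tiff(intensity_path, img.intensity)
    write_labels_tiff(labels_path, img.labels)


def read_labeled_image(
    intensity_path, labels_path, pixel_size_um: float | None = None
) -> LabeledImage:
    intensity = tifffile.imread(str(intensity_path)).astype(float)
    labels = tifffile.imread(str(labels_path)).astype(np.int64)
    return LabeledImage(intensity=intensity, labels=labels, pixel_size_um=pixel_size_um)


def write_traces_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRACE_COLUMNS)


def read_traces_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def load_config(path) -> dict:
    """Load a YAML (or JSON; YAML is a superset) config mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
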