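"""Reading and writing of every artifact the pipeline touches.

Frames, label masks and displacement fields travel as TIFF; feature tables
as CSV; track graphs as JSON.  Coordinate convention throughout the package:
(row, col), 0-based, origin at the top-left corner; displacement vectors are
expressed in pixel units in the same convention.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageFrame",
    "SequenceManifest",
    "read_sequence",
    "read_label_mask",
    "write_label_mask",
    "read_displacement_field",
    "write_displacement_field",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_COLUMNS",
]


@dataclass
class ImageFrame:
    """One grayscale frame of a time-lapse sequence.

    ``pixels`` is a 2-D float array rescaled to [0, 1] at load time,
    whatever the native bit depth of the file was.
    """

    pixels: np.ndarray
    time_index: int = 0
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D grayscale array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SequenceManifest:
    """Ordered list of frame paths plus acquisition-interval metadata."""

    frame_paths: list[str] = field(default_factory=list)
    frame_interval: float = 1.0
    interval_unit: str = "frame"

    def __post_init__(self) -> None:
        if len(set(self.frame_paths)) != len(self.frame_paths):
            raise ValueError("frame paths must be unique")


_NAT_SPLIT = re.compile(r"(\d+)")


def _natural_key(path: Path) -> list:
    return [int(t) if t.isdigit() else t.lower() for t in _NAT_SPLIT.split(path.name)]


def _rescale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Map native integer bit depth to [0, 1]; float input is clipped."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _read_gray(path: Path) -> np.ndarray:
    arr = tifffile.imread(str(path)) if path.suffix.lower() in {".tif", ".tiff"} else None
    if arr is None:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    if arr.ndim == 3:  # collapse an RGB(A) image that is actually gray
        arr = arr[..., :3].mean(axis=-1).astype(arr.dtype)
    if arr.ndim != 2:
        raise ValueError(f"{path}: not a 2-D grayscale image")
    return arr


def read_sequence(pattern: str | Path) -> list[ImageFrame]:
    """Read an ordered frame sequence from a directory or glob pattern.

    Files are sorted in natural (human) filename order and assigned
    ``time_index`` 0..n-1.  All frames must share one shape.
    """
    pattern = Path(pattern)
    if pattern.is_dir():
        paths = [p for p in pattern.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}]
    else:
        paths = [Path(p) for p in pattern.parent.glob(pattern.name)]
    paths = sorted(paths, key=_natural_key)
    if not paths:
        raise FileNotFoundError(f"no frames match {pattern}")
    frames: list[ImageFrame] = []
    for i, p in enumerate(paths):
        pix = _rescale_to_unit(_read_gray(p))
        if frames and pix.shape != frames[0].pixels.shape:
            raise ValueError(
                f"{p}: frame shape {pix.shape} differs from first frame "
                f"{frames[0].pixels.shape}"
            )
        frames.append(ImageFrame(pixels=pix, time_index=i, source_path=str(p)))
    return frames


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as a 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit capacity (65535)")
    if labels.min(initial=0) < 0:
        raise ValueError("label values must be non-negative")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(str(path))
    if labels.ndim != 2:
        raise ValueError(f"{path}: label mask must be single-channel")
    return labels.astype(np.int32)


def write_displacement_field(u: np.ndarray, path: str | Path) -> None:
    """Write a displacement field as a 2-channel 32-bit float TIFF.

    Channel 0 holds row displacements, channel 1 column displacements.
    """
    u = np.asarray(u, dtype=np.float32)
    if u.ndim != 3 or u.shape[0] != 2:
        raise ValueError("displacement field must have shape (2, H, W)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    # one grayscale page per channel; keeps the (2, H, W) layout on read
    tifffile.imwrite(str(path), u, photometric="minisblack")


def read_displacement_field(path: str | Path) -> np.ndarray:
    u = tifffile.imread(str(path)).astype(np.float32)
    if u.ndim != 3 or u.shape[0] != 2:
        raise ValueError(f"{path}: expected a (2, H, W) displacement field")
    return u


FEATURE_COLUMNS = [
    "frame",
    "colony_id",
    "area_px",
    "elongation",
    "circularity",
    "entropy",
    "mean_displacement",
    "sd_displacement",
    "centroid_row",
    "centroid_col",
]


def write_feature_table(records: Sequence, path: str | Path) -> None:
    """Write per-colony per-frame feature records to CSV (one row each)."""
    import pandas as pd

    if not records:
        raise ValueError("no feature records to write")
    rows = []
    for r in records:
        rows.append(
            {
                "frame": r.frame_index,
                "colony_id": r.colony_id,
                "area_px": r.area_px,
                "elongation": r.elongation,
                "circularity": r.circularity,
                "entropy": r.entropy,
                "mean_displacement": r.mean_displacement,
                "sd_displacement": r.sd_displacement,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)
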