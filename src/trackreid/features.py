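"""54-dimensional RGB grid appearance descriptor.

Each bounding box is divided into a 3x3 grid; in every cell the mean and the
(population) standard deviation of each colour plane are computed, giving
9 cells x 3 colours x 2 statistics = 54 features on the raw 0-255 intensity
scale.  The descriptor is deliberately simple: with heavily overlapping
boxes of visually similar animals, elaborate appearance models gain little,
while colour statistics remain stable and cheap inside an iterative merge
loop.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import FEATURE_DIM, BoundingBox, TrackedDataset, ValidationError

__all__ = [
    "extract_features",
    "featurize_dataset",
    "feature_names",
    "write_feature_table",
    "read_feature_table",
    "zscore",
]

_GRID = 3
_CHANNELS = ("R", "G", "B")
_STATS = ("mean", "std")


def feature_names() -> list[str]:
    """Column names, cell-major then channel-major then (mean, std)."""
    return [
        f"cell{c + 1}_{ch}_{st}"
        for c in range(_GRID * _GRID)
        for ch in _CHANNELS
        for st in _STATS
    ]


def _pixel_extent(box: BoundingBox, width: int, height: int) -> tuple[int, int, int, int]:
    """Integer pixel extent of the box clamped to the image, half-open."""
    x0 = max(0, int(np.ceil(box.x - 1e-9)))
    y0 = max(0, int(np.ceil(box.y - 1e-9)))
    x1 = min(width, int(np.ceil(box.x + box.w - 1e-9)))
    y1 = min(height, int(np.ceil(box.y + box.h - 1e-9)))
    return x0, y0, x1, y1


def extract_features(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Compute the 54-value grid descriptor of ``box`` within ``image``.

    The box is clamped to the image bounds; the clamped extent must be at
    least 3x3 pixels.  Cell boundaries fall at ``floor(i*w/3)`` so cells may
    differ by one pixel but always partition the box.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    height, width = img.shape[:2]
    x0, y0, x1, y1 = _pixel_extent(box, width, height)
    if x1 - x0 < _GRID or y1 - y0 < _GRID:
        raise ValidationError(
            f"box clamped to image is {x1 - x0}x{y1 - y0} pixels; need at least 3x3"
        )
    patch = img[y0:y1, x0:x1].astype(np.float64)
    ph, pw = patch.shape[:2]
    xs = [pw * i // _GRID for i in range(_GRID + 1)]
    ys = [ph * i // _GRID for i in range(_GRID + 1)]
    out = np.empty(FEATURE_DIM)
    k = 0
    for r in range(_GRID):
        for c in range(_GRID):
            cell = patch[ys[r] : ys[r + 1], xs[c] : xs[c + 1]]
            for ch in range(3):
                plane = cell[:, :, ch]
                out[k] = plane.mean()
                out[k + 1] = plane.std()  # population form: a descriptor, not an estimator
                k += 2
    return out


_FRAME_FILE = re.compile(r"^(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


def _frame_index(frames_dir: str | os.PathLike) -> dict[int, Path]:
    index: dict[int, Path] = {}
    for p in sorted(Path(frames_dir).iterdir()):
        m = _FRAME_FILE.match(p.name)
        if m:
            index.setdefault(int(m.group(1)), p)
    return index


def featurize_dataset(
    dataset: TrackedDataset, frames_dir: str | os.PathLike
) -> TrackedDataset:
    """Attach a feature vector to every detection, reading frame images.

    Frames are numbered image files (``000017.png`` etc.) in ``frames_dir``;
    each image is loaded once.  Idempotent: already-featurized detections
    are recomputed identically.
    """
    import imageio.v3 as iio

    index = _frame_index(frames_dir)
    for frame in sorted({d.frame for d in dataset}):
        if frame not in index:
            raise IOError(f"no image for frame {frame} in {frames_dir}")
        img = np.asarray(iio.imread(index[frame]))
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[:, :, :3]
        for det in dataset.in_frame(frame):
            det.features = extract_features(img, det.box)
    return dataset


def write_feature_table(dataset: TrackedDataset, path: str | os.PathLike) -> None:
    """Write one row of 54 named feature columns per detection (CSV)."""
    df = pd.DataFrame(dataset.feature_matrix(), columns=feature_names())
    df.to_csv(path, index=False, float_format="%.6f")


def read_feature_table(path: str | os.PathLike) -> np.ndarray:
    df = pd.read_csv(path)
    if df.shape[1] != FEATURE_DIM:
        raise ValidationError(
            f"feature table must have {FEATURE_DIM} columns, got {df.shape[1]}"
        )
    return df.to_numpy(dtype=float)


def zscore(X: np.ndarray) -> np.ndarray:
    """Per-column standardization; constant columns are left centred at 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd
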