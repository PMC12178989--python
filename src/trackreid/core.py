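"""Domain types for video detections and tracks, plus annotation I/O.

A video is a set of consecutive frames; a multiple-object tracker (or a
manual annotator) supplies, for every animal in every frame, an axis-aligned
bounding box together with a track label and — for annotated ground truth —
an identity label.  :class:`TrackedDataset` is the in-memory container the
whole pipeline operates on; annotations travel on disk as MOTChallenge-style
CSV (``frame, id, bb_left, bb_top, bb_width, bb_height, ...``).
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "BoundingBox",
    "Detection",
    "TrackedDataset",
    "as_label_vector",
    "read_annotations",
    "write_labels",
]

#: length of the appearance descriptor used throughout the package
FEATURE_DIM = 54


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ParseError(ValueError):
    """An annotation file could not be parsed."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with half-open extent ``[x, x+w) x [y, y+h)``.

    Coordinates are 0-based pixels; ``w`` and ``h`` must be positive.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"bounding box field {name!r} is not finite: {v}")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(
                f"bounding box must have positive extent, got w={self.w}, h={self.h}"
            )

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass
class Detection:
    """One bounding-box observation of one animal in one frame.

    ``track`` is the tracker's label, ``identity`` the annotated ground
    truth; either may be unset.  ``features`` holds the appearance
    descriptor once the detection has been featurized.
    """

    frame: int
    box: BoundingBox
    track: Optional[int] = None
    identity: Optional[int] = None
    features: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"frame index must be non-negative, got {self.frame}")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape != (FEATURE_DIM,):
                raise ValidationError(
                    f"feature vector must have length {FEATURE_DIM}, "
                    f"got shape {self.features.shape}"
                )


class TrackedDataset:
    """Ordered collection of detections with frame and track lookups."""

    def __init__(self, detections: Sequence[Detection], n_frames: Optional[int] = None):
        detections = list(detections)
        if not detections:
            raise ValidationError("a TrackedDataset needs at least one detection")
        max_frame = max(d.frame for d in detections)
        if n_frames is None:
            n_frames = max_frame + 1
        elif n_frames <= max_frame:
            raise ValidationError(
                f"n_frames={n_frames} but detections reach frame {max_frame}"
            )
        self.detections: list[Detection] = detections
        self.n_frames: int = n_frames
        self._by_frame: dict[int, list[int]] = {}
        self._by_track: dict[int, list[int]] = {}
        for i, d in enumerate(detections):
            self._by_frame.setdefault(d.frame, []).append(i)
            if d.track is not None:
                self._by_track.setdefault(d.track, []).append(i)
        # a track's detections are served in frame order
        for idxs in self._by_track.values():
            idxs.sort(key=lambda i: detections[i].frame)

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def __getitem__(self, i: int) -> Detection:
        return self.detections[i]

    @property
    def frames(self) -> list[int]:
        """Sorted frame indices that contain at least one detection."""
        return sorted(self._by_frame)

    def in_frame(self, frame: int) -> list[Detection]:
        return [self.detections[i] for i in self._by_frame.get(frame, [])]

    def indices_in_frame(self, frame: int) -> list[int]:
        return list(self._by_frame.get(frame, []))

    def in_track(self, track: int) -> list[Detection]:
        return [self.detections[i] for i in self._by_track.get(track, [])]

    def track_ids(self) -> list[int]:
        return sorted(self._by_track)

    def frame_vector(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    def track_labels(self) -> np.ndarray:
        """Per-detection track labels; raises if any detection lacks one."""
        if any(d.track is None for d in self.detections):
            raise ValidationError("dataset contains detections without a track label")
        return np.array([d.track for d in self.detections], dtype=int)

    def identity_labels(self) -> np.ndarray:
        if any(d.identity is None for d in self.detections):
            raise ValidationError("dataset contains detections without ground truth")
        return np.array([d.identity for d in self.detections], dtype=int)

    def feature_matrix(self) -> np.ndarray:
        if any(d.features is None for d in self.detections):
            raise ValidationError(
                "dataset is not featurized; run featurize_dataset first"
            )
        return np.stack([d.features for d in self.detections])

    def is_featurized(self) -> bool:
        return all(d.features is not None for d in self.detections)

    def with_tracks(self, labels: Sequence[int]) -> "TrackedDataset":
        """Return a copy whose detections carry ``labels`` as track labels."""
        labels = as_label_vector(labels, len(self))
        dets = [replace(d, track=int(l)) for d, l in zip(self.detections, labels)]
        return TrackedDataset(dets, n_frames=self.n_frames)


def as_label_vector(labels: Sequence[int], n: Optional[int] = None) -> np.ndarray:
    """Validate and convert a per-detection label sequence to an int array."""
    arr = np.asarray(labels)
    if arr.ndim != 1:
        raise ValidationError(f"labels must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError("label vector is empty")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == arr.astype(int)):
            raise ValidationError("labels must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ValidationError("labels must be non-negative")
    if n is not None and arr.shape[0] != n:
        raise ValidationError(f"expected {n} labels, got {arr.shape[0]}")
    return arr.astype(int, copy=True)


def read_annotations(
    path: str | os.PathLike,
    frames_dir: Optional[str | os.PathLike] = None,
    *,
    id_field: str = "identity",
    frame_base: int = 1,
) -> TrackedDataset:
    """Read a MOTChallenge-style CSV into a :class:`TrackedDataset`.

    Each row is ``frame, id, x, y, w, h`` (extra columns ignored).  The id
    column becomes ``Detection.identity`` by default or ``Detection.track``
    when ``id_field="track"``.  ``frame_base`` is subtracted from the frame
    column (MOTChallenge files are 1-based; the package is 0-based
    internally).  Detections are returned frame-major, then in file order.
    """
    if id_field not in ("identity", "track"):
        raise ValidationError(f"id_field must be 'identity' or 'track', got {id_field!r}")
    rows: list[tuple[int, int, Detection]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and not _looks_numeric(row[0]):
                continue  # header row
            if len(row) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 columns, got {len(row)}")
            try:
                frame = int(float(row[0])) - frame_base
                obj_id = int(float(row[1]))
                x, y, w, h = (float(v) for v in row[2:6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if frame < 0:
                raise ParseError(
                    f"{path}: line {lineno}: frame {frame + frame_base} below frame base {frame_base}"
                )
            if w <= 0 or h <= 0:
                raise ValidationError(
                    f"{path}: line {lineno}: non-positive box extent w={w}, h={h}"
                )
            det = Detection(
                frame=frame,
                box=BoundingBox(x, y, w, h),
                identity=obj_id if id_field == "identity" else None,
                track=obj_id if id_field == "track" else None,
            )
            rows.append((frame, lineno, det))
    if not rows:
        raise ValidationError(f"{path}: no detections found")
    rows.sort(key=lambda t: (t[0], t[1]))
    dataset = TrackedDataset([d for _, _, d in rows])
    if frames_dir is not None:
        from .features import featurize_dataset

        dataset = featurize_dataset(dataset, frames_dir)
    return dataset


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_labels(
    dataset: TrackedDataset,
    labels: Sequence[int],
    path: str | os.PathLike,
    *,
    frame_base: int = 1,
) -> None:
    """Write the per-detection label map as CSV.

    Columns: ``frame, assigned_label, x, y, w, h, ground_truth`` (ground
    truth blank when unset); one row per detection, in dataset order, boxes
    printed with two decimals.
    """
    labels = as_label_vector(labels, len(dataset))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "assigned_label", "x", "y", "w", "h", "ground_truth"])
        for det, lab in zip(dataset.detections, labels):
            b = det.box
            writer.writerow(
                [
                    det.frame + frame_base,
                    int(lab),
                    f"{b.x:.2f}",
                    f"{b.y:.2f}",
                    f"{b.w:.2f}",
                    f"{b.h:.2f}",
                    "" if det.identity is None else det.identity,
                ]
            )
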