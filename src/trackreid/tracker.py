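"""IoU-gated Hungarian track builder across consecutive frames.

Boxes in adjacent frames are associated one-to-one so that the total
intersection-over-union of matched pairs is maximal, with pairs below the
IoU threshold (default 0.7) inadmissible.  A chain of matched boxes forms a
track; a box unmatched in the previous frame starts a new track.  This is
the simplest tracker that exploits only spatial continuity — appearance
plays no role — and it is the track generator the rest of the pipeline
post-processes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, Detection, TrackedDataset, ValidationError

__all__ = ["iou", "associate_frames", "build_tracks", "AssociationResult"]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, from continuous areas."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass
class AssociationResult:
    """One-to-one matches between a previous and a current frame."""

    matches: list[tuple[int, int]]
    unmatched_current: list[int]


# Lexicographic tie-break bonus: among assignments of equal total IoU, prefer
# lower previous index, then lower current index. Small enough never to
# override a genuine IoU difference at realistic precision.
_TIE_EPS = 1e-9


def associate_frames(
    prev: Sequence[Detection],
    cur: Sequence[Detection],
    threshold: float = 0.7,
) -> AssociationResult:
    """Optimal IoU assignment between two frames' detections.

    Returns the one-to-one matching maximizing total IoU over admissible
    pairs (IoU >= threshold); current detections left unmatched start new
    tracks.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    n_prev, n_cur = len(prev), len(cur)
    if n_prev == 0 or n_cur == 0:
        return AssociationResult(matches=[], unmatched_current=list(range(n_cur)))
    gain = np.zeros((n_prev, n_cur))
    for i, dp in enumerate(prev):
        for j, dc in enumerate(cur):
            v = iou(dp.box, dc.box)
            if v >= threshold:
                gain[i, j] = v + _TIE_EPS * ((n_prev - i) + (n_cur - j) / (n_cur + 1.0))
    rows, cols = linear_sum_assignment(gain, maximize=True)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols) if gain[i, j] > 0]
    matched_cur = {j for _, j in matches}
    unmatched = [j for j in range(n_cur) if j not in matched_cur]
    return AssociationResult(matches=matches, unmatched_current=unmatched)


def build_tracks(dataset: TrackedDataset, threshold: float = 0.7) -> np.ndarray:
    """Assign a track label to every detection by chaining adjacent-frame matches.

    Association is strictly between consecutive frame indices: across a gap
    (a frame with no detections, or a missing frame number) every detection
    starts a new track.  Labels are issued in order of track creation,
    starting at 0.
    """
    labels = np.full(len(dataset), -1, dtype=int)
    next_label = 0
    prev_frame: int | None = None
    prev_indices: list[int] = []
    for frame in dataset.frames:
        cur_indices = dataset.indices_in_frame(frame)
        cur_dets = [dataset[i] for i in cur_indices]
        if prev_frame is not None and frame == prev_frame + 1 and prev_indices:
            prev_dets = [dataset[i] for i in prev_indices]
            assoc = associate_frames(prev_dets, cur_dets, threshold)
            for pi, ci in assoc.matches:
                labels[cur_indices[ci]] = labels[prev_indices[pi]]
        for i in cur_indices:
            if labels[i] < 0:
                labels[i] = next_label
                next_label += 1
        prev_frame = frame
        prev_indices = cur_indices
    return labels
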