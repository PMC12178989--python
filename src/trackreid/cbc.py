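"""Classifier-based clustering (CBC) of tracks under cannot-link constraints.

Tracks produced by a tracker over-segment the identities in a video: an
animal that leaves the view, is occluded, or moves abruptly starts a new
track.  CBC merges tracks back down to the (approximately known) number of
identities K by exploiting appearance.  At each step a classifier is trained
on the feature vectors using the *current* track labels as classes and
applied back to the same data (resubstitution).  The row-scaled confusion
matrix then reads as "what proportion of track p looks like track q"; the
largest off-diagonal entry nominates the next merge.  Two tracks that ever
co-occur in a frame cannot be the same animal, so their entries are masked
to zero (cannot-link constraints) and the corresponding merge can never
happen.  The loop stops when K tracks remain or nothing mergeable is left.

Because merges only ever relabel a whole track, the output is a coarsening
of the input tracks; the within-track must-link structure is preserved for
free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid

from .core import TrackedDataset, ValidationError, as_label_vector

__all__ = [
    "MergeMatrix",
    "make_classifier",
    "track_cl_constraints",
    "merge_matrix",
    "cbc_cluster",
]


@dataclass
class MergeMatrix:
    """Masked, row-scaled resubstitution confusion matrix over tracks.

    ``values[i, j]`` is the proportion of track ``keys[i]``'s members that
    the classifier relabels as ``keys[j]``, after the diagonal and all
    cannot-link pairs are zeroed.  Rows with no admissible confusion are
    all-zero rather than renormalized.
    """

    values: np.ndarray
    keys: list[int]

    def largest(self) -> tuple[int, int, float]:
        """(row key, column key, value) of the largest entry.

        Ties broken toward the lowest row key, then lowest column key
        (keys are sorted, so the first row-major maximum is that entry).
        """
        flat = int(np.argmax(self.values))
        i, j = divmod(flat, self.values.shape[1])
        return self.keys[i], self.keys[j], float(self.values[i, j])


def make_classifier(name: str = "nearest-centroid", **hyperparams) -> BaseEstimator:
    """Build a classifier for the CBC loop by name.

    ``nearest-centroid`` is the default: it tolerates singleton classes
    (fragmented videos routinely yield tracks of one box), trains in linear
    time, and judges purely by appearance similarity.  ``knn`` is offered
    for experimentation; note that 1-NN is degenerate under resubstitution
    (every point is its own nearest neighbour), so k defaults to 3.
    """
    name = name.lower().replace("_", "-")
    if name == "nearest-centroid":
        return NearestCentroid(**hyperparams)
    if name == "knn":
        hyperparams.setdefault("n_neighbors", 3)
        return KNeighborsClassifier(**hyperparams)
    raise ValidationError(f"unknown classifier {name!r}")


def track_cl_constraints(
    frames: Sequence[int] | TrackedDataset,
    labels: Sequence[int],
) -> set[tuple[int, int]]:
    """Cannot-link pairs: tracks that co-occur in at least one frame.

    ``frames`` may be a dataset or a per-detection frame vector.  Returns
    unordered pairs as sorted tuples ``(p, q)`` with ``p < q``.
    """
    if isinstance(frames, TrackedDataset):
        frames = frames.frame_vector()
    frames = np.asarray(frames, dtype=int)
    labels = as_label_vector(labels, len(frames))
    pairs: set[tuple[int, int]] = set()
    for f in np.unique(frames):
        present = np.unique(labels[frames == f])
        if present.size < 2:
            continue
        for a_idx in range(present.size):
            for b_idx in range(a_idx + 1, present.size):
                pairs.add((int(present[a_idx]), int(present[b_idx])))
    return pairs


def merge_matrix(
    X: np.ndarray,
    labels: Sequence[int],
    cl: set[tuple[int, int]],
    clf: BaseEstimator,
) -> MergeMatrix:
    """Train ``clf`` on (X, labels), resubstitute, mask and row-scale.

    Steps: confusion counts from resubstitution; diagonal zeroed (correct
    classifications carry no merge information); cannot-link pairs zeroed
    symmetrically; each row scaled to sum to 1, all-zero rows left as zero.
    """
    X = np.asarray(X, dtype=float)
    labels = as_label_vector(labels, X.shape[0])
    keys = sorted(int(k) for k in np.unique(labels))
    if len(keys) < 2:
        raise ValidationError("merge matrix needs at least 2 distinct track labels")
    model = clone(clf)
    try:
        with warnings.catch_warnings():
            # fragmented videos legitimately have more tracks than half the
            # boxes; sklearn's "could be regression" heuristic does not apply
            warnings.simplefilter("ignore", UserWarning)
            model.fit(X, labels)
            pred = model.predict(X)
    except Exception as exc:  # pragma: no cover - depends on classifier
        raise RuntimeError(f"classifier failed inside the merge loop: {exc}") from exc
    counts = confusion_matrix(labels, pred, labels=keys).astype(float)
    np.fill_diagonal(counts, 0.0)
    pos = {k: i for i, k in enumerate(keys)}
    for p, q in cl:
        if p in pos and q in pos:
            counts[pos[p], pos[q]] = 0.0
            counts[pos[q], pos[p]] = 0.0
    sums = counts.sum(axis=1)
    nz = sums > 0
    counts[nz] = counts[nz] / sums[nz, None]
    return MergeMatrix(values=counts, keys=keys)


def cbc_cluster(
    dataset: TrackedDataset,
    track_labels: Sequence[int],
    K: int,
    clf: Optional[BaseEstimator] = None,
) -> np.ndarray:
    """Merge tracks down to K identities by iterated classifier confusion.

    If K is at least the number of input tracks the labels are returned
    unchanged.  Otherwise tracks are merged pairwise — the row track of the
    largest merge-matrix entry is relabelled to its column track — with
    cannot-link constraints recomputed from the merged tracks' combined
    frame sets each iteration.  Stops at K tracks, or earlier if every
    remaining entry is zero (all merges blocked).  At most
    ``n_tracks - K`` merges are performed.
    """
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    if clf is None:
        clf = make_classifier()
    X = dataset.feature_matrix()
    frames = dataset.frame_vector()
    labels = as_label_vector(track_labels, len(dataset))
    while np.unique(labels).size > K:
        cl = track_cl_constraints(frames, labels)
        M = merge_matrix(X, labels, cl, clf)
        p, q, value = M.largest()
        if value <= 0.0:
            break  # nothing admissible left to merge
        labels[labels == p] = q
    return labels
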