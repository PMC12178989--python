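"""External clustering evaluation for label maps.

The assigned labels of a video (tracks, or clusters of tracks) are compared
with the annotated ground truth through four standard external metrics:

* ARI  — Hubert–Arabie adjusted Rand index, chance-corrected pairwise
  agreement in [-1, 1];
* NMI  — mutual information normalized by the arithmetic mean of the two
  label entropies, in [0, 1];
* ACC  — counting accuracy under a many-to-one majority mapping of clusters
  to classes;
* HACC — accuracy under the optimal one-to-one (Hungarian) mapping.

ACC and HACC reward degenerate labelings (all-singletons scores ACC = 1 for
any truth), and NMI is inflated by fine partitions, which is why a sanity
battery of constructed labelings (random, constant, all-different,
random-track) is provided: only ARI scores all four at zero.  A seeded
incremental Friedman procedure identifies the statistically
indistinguishable top group of methods from a per-dataset rank matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2, rankdata
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .core import ValidationError

__all__ = [
    "contingency_table",
    "ari",
    "nmi",
    "counting_accuracy",
    "hungarian_accuracy",
    "metric_report",
    "sanity_battery",
    "friedman_pvalue",
    "incremental_friedman",
]


def _check_pair(tl: Sequence[int], al: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    tl = np.asarray(tl)
    al = np.asarray(al)
    if tl.ndim != 1 or al.ndim != 1:
        raise ValidationError("label vectors must be one-dimensional")
    if tl.shape[0] != al.shape[0]:
        raise ValidationError(
            f"label vectors differ in length: {tl.shape[0]} vs {al.shape[0]}"
        )
    if tl.shape[0] == 0:
        raise ValidationError("label vectors are empty")
    return tl, al


@dataclass
class ContingencyTable:
    """Counts of detections by (true class, assigned label)."""

    counts: np.ndarray
    true_keys: list
    assigned_keys: list


def contingency_table(tl: Sequence[int], al: Sequence[int]) -> ContingencyTable:
    tl, al = _check_pair(tl, al)
    tk, ti = np.unique(tl, return_inverse=True)
    ak, ai = np.unique(al, return_inverse=True)
    counts = np.zeros((tk.size, ak.size), dtype=int)
    np.add.at(counts, (ti, ai), 1)
    return ContingencyTable(counts=counts, true_keys=list(tk), assigned_keys=list(ak))


def ari(tl: Sequence[int], al: Sequence[int]) -> float:
    """Hubert–Arabie adjusted Rand index; symmetric, relabel-invariant.

    Trivial partitions (one cluster, or all singletons) score 0 against any
    non-trivial truth; two identical trivial partitions score 1.
    """
    tl, al = _check_pair(tl, al)
    if tl.shape[0] < 2:
        raise ValidationError("ARI needs at least 2 points")
    return float(adjusted_rand_score(tl, al))


def nmi(tl: Sequence[int], al: Sequence[int]) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    tl, al = _check_pair(tl, al)
    return float(normalized_mutual_info_score(tl, al, average_method="arithmetic"))


def counting_accuracy(tl: Sequence[int], al: Sequence[int]) -> float:
    """Majority mapping: each assigned cluster votes for its modal true class."""
    table = contingency_table(tl, al)
    return float(table.counts.max(axis=0).sum() / table.counts.sum())


def hungarian_accuracy(tl: Sequence[int], al: Sequence[int]) -> float:
    """Optimal one-to-one mapping of clusters to classes (unmatched score 0)."""
    table = contingency_table(tl, al)
    rows, cols = linear_sum_assignment(table.counts, maximize=True)
    return float(table.counts[rows, cols].sum() / table.counts.sum())


def metric_report(tl: Sequence[int], al: Sequence[int]) -> dict[str, float]:
    """All four metrics as a dict keyed nmi/ari/acc/hacc."""
    return {
        "nmi": nmi(tl, al),
        "ari": ari(tl, al),
        "acc": counting_accuracy(tl, al),
        "hacc": hungarian_accuracy(tl, al),
    }


def sanity_battery(
    tl: Sequence[int],
    n_classes: int,
    n_tracks: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Score four constructed labelings against the truth with all metrics.

    RL: N uniform random labels in 1..n_classes.  SL: one constant label.
    DL: all-different labels (a random permutation of 1..N).  RA: N uniform
    random labels in 1..n_tracks.  Rows RL/SL/DL/RA, columns nmi/ari/acc/
    hacc; seeded and reproducible.
    """
    tl = np.asarray(tl)
    n = tl.shape[0]
    if n_classes < 1 or n < n_classes:
        raise ValidationError(f"need 1 <= n_classes <= N, got n_classes={n_classes}, N={n}")
    if n_tracks < 1 or n_tracks > n:
        raise ValidationError(f"need 1 <= n_tracks <= N, got n_tracks={n_tracks}, N={n}")
    rng = np.random.default_rng(seed)
    labelings = {
        "RL": rng.integers(1, n_classes + 1, size=n),
        "SL": np.ones(n, dtype=int),
        "DL": rng.permutation(n) + 1,
        "RA": rng.integers(1, n_tracks + 1, size=n),
    }
    rows = {name: metric_report(tl, al) for name, al in labelings.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[["nmi", "ari", "acc", "hacc"]]


def friedman_pvalue(ranks: np.ndarray) -> float:
    """Friedman chi-square p-value for a (datasets x methods) score matrix.

    Rows are re-ranked internally (average ranks on ties); the classical
    chi-square approximation with the standard tie correction is used.  A
    matrix in which every row is entirely tied returns p = 1.
    """
    mat = np.asarray(ranks, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("rank matrix must be 2-D (datasets x methods)")
    n, k = mat.shape
    if k < 2:
        raise ValidationError("Friedman test needs at least 2 methods")
    if n < 2:
        raise ValidationError("Friedman test needs at least 2 datasets")
    R = np.apply_along_axis(rankdata, 1, mat)
    ssbn = float((R.sum(axis=0) ** 2).sum())
    stat = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    ties = 0.0
    for row in mat:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (k * (k * k - 1) * n)
    if c == 0.0:
        return 1.0  # every row fully tied: no evidence of any difference
    return float(chi2.sf(stat / c, k - 1))


def incremental_friedman(ranks: np.ndarray, alpha: float = 0.05) -> int:
    """Size of the indistinguishable top group of methods.

    ``ranks`` has one row per dataset and one column per method, columns
    ordered best first.  Starting from the best two methods, one method is
    added at a time and the Friedman p-value recomputed on the prefix; the
    procedure returns the largest prefix whose p-value stays >= alpha
    (1 if even the best two already differ significantly).
    """
    mat = np.asarray(ranks, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValidationError("need a 2-D rank matrix with at least 2 methods")
    k = mat.shape[1]
    for m in range(2, k + 1):
        if friedman_pvalue(mat[:, :m]) < alpha:
            return m - 1
    return k
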