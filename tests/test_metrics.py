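import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, friedmanchisquare

from trackreid import (
    ValidationError,
    ari,
    counting_accuracy,
    friedman_pvalue,
    hungarian_accuracy,
    incremental_friedman,
    metric_report,
    nmi,
    sanity_battery,
)


def ari_pair_enumeration(tl, al):
    """ARI by brute-force enumeration of all point pairs."""
    n = len(tl)
    a = b = c = d = 0  # same-same, same-diff, diff-same, diff-diff
    for i, j in itertools.combinations(range(n), 2):
        st, sa = tl[i] == tl[j], al[i] == al[j]
        if st and sa:
            a += 1
        elif st and not sa:
            b += 1
        elif not st and sa:
            c += 1
        else:
            d += 1
    total = a + b + c + d
    index = a
    expected = (a + b) * (a + c) / total
    maximum = ((a + b) + (a + c)) / 2
    if maximum == expected:
        return 1.0 if b == c == 0 else 0.0
    return (index - expected) / (maximum - expected)


def hacc_exhaustive(tl, al):
    """HACC by exhaustive search over one-to-one cluster-class mappings."""
    tks, aks = sorted(set(tl)), sorted(set(al))
    counts = {(t, c): 0 for t in tks for c in aks}
    for t, c in zip(tl, al):
        counts[(t, c)] += 1
    best = 0
    r = min(len(tks), len(aks))
    for t_sub in itertools.combinations(tks, r):
        for a_perm in itertools.permutations(aks, r):
            best = max(best, sum(counts[(t, c)] for t, c in zip(t_sub, a_perm)))
    return best / len(tl)


@pytest.fixture
def truth_699(rng):
    """699 objects in 8 non-empty classes, as in an eight-animal pen video."""
    tl = rng.integers(1, 9, size=699)
    for k in range(1, 9):  # guarantee non-empty classes
        tl[k - 1] = k
    return tl


class TestAnalyticCells:
    def test_one_cluster_labeling_scores_ari_zero(self, truth_699):
        assert ari(truth_699, np.ones(699, dtype=int)) == pytest.approx(0.0, abs=5e-5)

    def test_all_singletons_scores_ari_zero_acc_one(self, truth_699):
        dl = np.arange(1, 700)
        assert ari(truth_699, dl) == pytest.approx(0.0, abs=5e-5)
        assert counting_accuracy(truth_699, dl) == 1.0

    def test_all_singletons_hacc_is_classes_over_n(self, truth_699):
        assert round(hungarian_accuracy(truth_699, np.arange(1, 700)), 4) == 0.0114


class TestARI:
    def test_identity_labeling(self):
        assert ari([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_relabeling_and_symmetry(self, rng):
        tl = rng.integers(0, 4, 30)
        al = rng.integers(0, 5, 30)
        assert ari(tl, al) == pytest.approx(ari(al, tl))
        assert ari(tl + 17, al) == pytest.approx(ari(tl, al))

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 31))
            tl = rng.integers(0, 8, n)
            al = rng.integers(0, 8, n)
            assert ari(tl, al) == pytest.approx(ari_pair_enumeration(tl, al), abs=1e-10)

    def test_degenerate_identical_trivial_partitions(self):
        assert ari([1, 1, 1], [5, 5, 5]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            ari([1, 2], [1, 2, 3])


class TestNMI:
    def test_identical_nontrivial_is_one(self):
        assert nmi([1, 1, 2, 2], [7, 7, 3, 3]) == pytest.approx(1.0)

    def test_constant_assignment_is_zero(self):
        assert nmi([1, 2, 1, 2], [4, 4, 4, 4]) == 0.0

    def test_hand_computed_four_point_example(self):
        # tl = [0,0,1,1], al = [0,0,1,0]; MI and entropies by hand
        tl, al = [0, 0, 1, 1], [0, 0, 1, 0]
        p = {(0, 0): 0.5, (1, 0): 0.25, (1, 1): 0.25}
        pt = {0: 0.5, 1: 0.5}
        pa = {0: 0.75, 1: 0.25}
        mi = sum(v * math.log(v / (pt[i] * pa[j])) for (i, j), v in p.items())
        ht = -sum(v * math.log(v) for v in pt.values())
        ha = -sum(v * math.log(v) for v in pa.values())
        assert nmi(tl, al) == pytest.approx(mi / ((ht + ha) / 2))


class TestAccuracies:
    def test_counting_accuracy_majority_mapping(self):
        assert counting_accuracy([1, 1, 2], [7, 7, 7]) == pytest.approx(2 / 3)
        assert counting_accuracy([1, 1, 2], [1, 1, 2]) == 1.0

    def test_hungarian_identity(self):
        assert hungarian_accuracy([1, 2, 3], [3, 1, 2]) == pytest.approx(1.0)

    def test_hungarian_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            tl = rng.integers(0, 6, n)
            al = rng.integers(0, 6, n)
            assert hungarian_accuracy(tl, al) == pytest.approx(hacc_exhaustive(tl, al))

    def test_hungarian_never_exceeds_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            tl = rng.integers(0, 5, n)
            al = rng.integers(0, 7, n)
            assert hungarian_accuracy(tl, al) <= counting_accuracy(tl, al) + 1e-12

    def test_relabel_invariance(self, rng):
        tl = rng.integers(0, 4, 40)
        al = rng.integers(0, 6, 40)
        perm = rng.permutation(10)
        assert counting_accuracy(tl, perm[al]) == pytest.approx(counting_accuracy(tl, al))
        assert hungarian_accuracy(tl, perm[al]) == pytest.approx(hungarian_accuracy(tl, al))


class TestSanityBattery:
    def test_all_different_labels_row(self, truth_699):
        table = sanity_battery(truth_699, n_classes=8, n_tracks=463, seed=1)
        assert table.loc["DL", "acc"] == 1.0
        assert table.loc["DL", "ari"] == pytest.approx(0.0, abs=5e-5)

    def test_same_labels_row(self, truth_699):
        table = sanity_battery(truth_699, n_classes=8, n_tracks=463, seed=1)
        assert table.loc["SL", "ari"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["SL", "nmi"] == 0.0

    def test_random_labels_ari_near_zero(self, truth_699):
        aris = [
            sanity_battery(truth_699, 8, 463, seed=s).loc["RL", "ari"]
            for s in range(10)
        ]
        assert all(abs(a) < 0.05 for a in aris)

    def test_reproducible(self, truth_699):
        a = sanity_battery(truth_699, 8, 463, seed=3)
        b = sanity_battery(truth_699, 8, 463, seed=3)
        assert a.equals(b)

    def test_invalid_counts_rejected(self, truth_699):
        with pytest.raises(ValidationError):
            sanity_battery(truth_699, n_classes=0, n_tracks=10)
        with pytest.raises(ValidationError):
            sanity_battery(truth_699, n_classes=8, n_tracks=1000)


class TestFriedman:
    def test_identical_rank_rows_keep_all_methods(self):
        ranks = np.tile([2.0, 2.0, 2.0, 2.0], (6, 1))
        assert friedman_pvalue(ranks) == 1.0
        assert incremental_friedman(ranks) == 4

    def test_strict_dominance_two_methods(self):
        # one method ranked 1 on all 15 datasets: chi2 = 15 on 1 df
        ranks = np.tile([1.0, 2.0], (15, 1))
        assert friedman_pvalue(ranks) == pytest.approx(float(chi2.sf(15.0, 1)))
        assert incremental_friedman(ranks, alpha=0.05) == 1

    def test_three_methods_closed_form(self):
        ranks = np.array(
            [[1, 2, 3], [1, 3, 2], [2, 1, 3], [1, 2, 3], [3, 1, 2], [1, 2, 3]],
            dtype=float,
        )
        n, k = ranks.shape
        col = ranks.sum(axis=0)
        stat = 12.0 / (n * k * (k + 1)) * float((col**2).sum()) - 3 * n * (k + 1)
        assert friedman_pvalue(ranks) == pytest.approx(float(chi2.sf(stat, k - 1)))

    def test_agrees_with_scipy_for_three_plus_methods(self, rng):
        scores = rng.normal(size=(10, 4))
        expected = friedmanchisquare(*(scores[:, j] for j in range(4))).pvalue
        assert friedman_pvalue(scores) == pytest.approx(expected)

    def test_incremental_stops_at_first_significant_prefix(self):
        # methods 1-3 tie; method 4 strictly dominated by everything
        base = np.array([[1.5, 1.5, 3.0, 4.0]] * 15)
        base[::2, [0, 1]] = base[::2, [1, 0]]
        size = incremental_friedman(base, alpha=0.05)
        assert 2 <= size <= 3
        assert friedman_pvalue(base[:, : size + 1]) < 0.05

    def test_needs_two_methods_and_two_datasets(self):
        with pytest.raises(ValidationError):
            friedman_pvalue(np.ones((5, 1)))
        with pytest.raises(ValidationError):
            friedman_pvalue(np.ones((1, 3)))


label_pairs = st.integers(2, 25).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 5), min_size=n, max_size=n),
        st.lists(st.integers(0, 5), min_size=n, max_size=n),
    )
)


@settings(derandomize=True, max_examples=50)
@given(label_pairs)
def test_metric_ranges_and_ari_symmetry_hold_for_any_labelings(pair):
    tl, al = pair
    rep = metric_report(tl, al)
    assert -1 <= rep["ari"] <= 1
    assert all(0 <= rep[k] <= 1 + 1e-12 for k in ("nmi", "acc", "hacc"))
    assert rep["hacc"] <= rep["acc"] + 1e-12
    assert ari(tl, al) == pytest.approx(ari(al, tl))


def test_metric_report_keys(rng):
    rep = metric_report(rng.integers(0, 3, 20), rng.integers(0, 3, 20))
    assert set(rep) == {"nmi", "ari", "acc", "hacc"}
    assert -1 <= rep["ari"] <= 1 and all(0 <= rep[k] <= 1 for k in ("nmi", "acc", "hacc"))
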