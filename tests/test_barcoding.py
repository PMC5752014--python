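import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from integrotax.barcoding import (barcode_gap, default_grid,
                                  group_distance_summary, k2p, k2p_matrix,
                                  optimize_threshold)
from integrotax.tables import DistanceMatrix, SequenceSet


def counting_oracle_k2p(a: str, b: str) -> float:
    """Independent per-site counting implementation of the two-parameter
    distance (pairwise deletion)."""
    pur = set("AG")
    n = p = q = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in pur) == (y in pur):
            p += 1
        else:
            q += 1
    if n == 0:
        return math.nan
    P, Q = p / n, q / n
    arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.nan
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


class TestK2P:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 25
        assert k2p(s, s) == 0.0

    def test_ten_transitions_in_hundred_sites(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90       # A<->G is a transition
        assert k2p(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-7)
        assert k2p(a, b) == pytest.approx(0.1115718, abs=1e-7)

    def test_ten_transversions_in_hundred_sites(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90       # A<->C is a transversion
        expected = -0.5 * math.log(0.9 * math.sqrt(0.8))
        assert k2p(a, b) == pytest.approx(expected, abs=1e-7)
        assert k2p(a, b) == pytest.approx(0.1084661, abs=1e-7)

    def test_pairwise_deletion_of_ambiguity_codes(self):
        # R vs A is deleted, never half-counted
        assert k2p("RA", "AA") == 0.0
        assert math.isnan(k2p("RN", "AA"))

    def test_saturated_distance_undefined(self):
        assert math.isnan(k2p("AG", "GA"))   # P=1 -> log argument <= 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            k2p("ACG", "AC")

    def test_matches_counting_oracle_on_random_pairs(self):
        rng = np.random.default_rng(99)
        alphabet = np.array(list("ACGTN-R"))
        for _ in range(1000):
            L = rng.integers(20, 120)
            a = "".join(rng.choice(alphabet, L, p=[.23, .23, .23, .23, .04, .02, .02]))
            b = "".join(rng.choice(alphabet, L, p=[.23, .23, .23, .23, .04, .02, .02]))
            d1, d2 = k2p(a, b), counting_oracle_k2p(a, b)
            assert (math.isnan(d1) and math.isnan(d2)) or d1 == pytest.approx(d2, abs=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 60))
        da, db = k2p(a, b), k2p(b, a)
        assert (math.isnan(da) and math.isnan(db)) or da == db

    def test_monotone_in_transitions_at_fixed_transversions(self):
        base = "A" * 100
        prev = -1.0
        for nts in range(0, 20, 2):
            d = k2p(base, "G" * nts + "C" * 5 + "A" * (95 - nts))
            assert d > prev
            prev = d


class TestK2PMatrix:
    def test_matrix_entries_match_pairwise_calls(self):
        seqs = SequenceSet(["a", "b", "c"],
                           ["ACGTACGTAC", "ACGTACGTGC", "TCGAACGTAC"])
        D = k2p_matrix(seqs)
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else k2p(seqs.sequences[i],
                                                  seqs.sequences[j])
                assert D.D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal(self, preset):
        D = k2p_matrix(preset["sequences"])
        assert len(D) == len(preset["sequences"])
        np.testing.assert_allclose(D.D, D.D.T)
        np.testing.assert_allclose(np.diag(D.D), 0.0)


class TestGroupSummary:
    def test_clean_separation_means(self):
        D = DistanceMatrix(list("abcd"), np.array([
            [0.0, 0.0, 0.5, 0.5],
            [0.0, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0]]))
        s = group_distance_summary(D, ["g1", "g1", "g2", "g2"])
        assert s.within_stats["mean"] == 0.0
        assert s.between_stats["mean"] == 0.5

    def test_label_permutation_conserves_pooled_multiset(self):
        rng = np.random.default_rng(5)
        n = 8
        M = rng.random((n, n))
        D = DistanceMatrix([f"i{k}" for k in range(n)],
                           np.triu(M, 1) + np.triu(M, 1).T)
        labels = ["a", "a", "a", "b", "b", "c", "c", "c"]
        s1 = group_distance_summary(D, labels)
        s2 = group_distance_summary(D, labels[::-1])
        pooled1 = np.sort(np.concatenate([s1.within, s1.between]))
        pooled2 = np.sort(np.concatenate([s2.within, s2.between]))
        np.testing.assert_allclose(pooled1, pooled2)

    def test_singleton_group_contributes_no_within(self):
        D = DistanceMatrix(list("abc"),
                           np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0.]]))
        s = group_distance_summary(D, ["g1", "g1", "solo"])
        assert s.within_stats["n"] == 1          # only the g1 pair
        assert s.between_stats["n"] == 2


class TestBarcodeGap:
    def test_two_clean_clusters_all_gaps_positive(self):
        D = DistanceMatrix(list("abcd"), np.array([
            [0.0, 0.01, 0.2, 0.3],
            [0.01, 0.0, 0.25, 0.2],
            [0.2, 0.25, 0.0, 0.008],
            [0.3, 0.2, 0.008, 0.0]]))
        recs, singles = barcode_gap(D, ["x", "x", "y", "y"])
        assert len(recs) == 4 and not singles
        assert all(r.has_gap for r in recs)

    def test_overlapping_clusters_flag_absence(self):
        D = DistanceMatrix(list("abc"), np.array([
            [0.0, 0.10, 0.05],
            [0.10, 0.0, 0.20],
            [0.05, 0.20, 0.0]]))
        recs, _ = barcode_gap(D, ["x", "x", "y"])
        by_id = {r.id: r for r in recs}
        assert by_id["a"].gap == pytest.approx(-0.05)  # closest y nearer than furthest x
        assert not by_id["a"].has_gap

    def test_singleton_excluded_and_reported(self):
        D = DistanceMatrix(list("abc"), np.array([
            [0.0, 0.01, 0.3], [0.01, 0.0, 0.3], [0.3, 0.3, 0.0]]))
        recs, singles = barcode_gap(D, ["x", "x", "solo"])
        assert singles == ["c"]
        assert {r.id for r in recs} == {"a", "b"}


def brute_force_threshold_counts(D, labels, t):
    """Exhaustive re-implementation of the four-way classification."""
    n = len(labels)
    counts = dict(true_pos=0, true_neg=0, false_pos=0, false_neg=0)
    for i in range(n):
        neigh = [j for j in range(n)
                 if j != i and not math.isnan(D[i][j]) and D[i][j] <= t]
        conspecific = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not conspecific:
            counts["true_neg" if not neigh else "false_pos"] += 1
        elif not neigh:
            counts["false_neg"] += 1
        elif all(labels[j] == labels[i] for j in neigh):
            counts["true_pos"] += 1
        else:
            counts["false_pos"] += 1
    return counts


class TestThresholdOptimization:
    def test_clean_gap_zero_error_inside_gap(self):
        # within <= 0.005, between >= 0.05: zero cumulative error in between
        D = np.array([[0.0, 0.004, 0.06, 0.07],
                      [0.004, 0.0, 0.05, 0.06],
                      [0.06, 0.05, 0.0, 0.005],
                      [0.07, 0.06, 0.005, 0.0]])
        dm = DistanceMatrix(list("abcd"), D)
        tt = optimize_threshold(dm, ["x", "x", "y", "y"],
                                default_grid(0.001, 0.049, 0.001))
        inside = tt.table[(tt.table.threshold > 0.005)
                          & (tt.table.threshold < 0.05)]
        assert (inside["cumulative_error"] == 0).all()

    def test_threshold_below_all_distances_all_false_neg(self):
        D = np.array([[0.0, 0.02, 0.03], [0.02, 0.0, 0.04], [0.03, 0.04, 0.0]])
        dm = DistanceMatrix(list("abc"), D)
        tt = optimize_threshold(dm, ["x", "x", "x"], [0.001])
        row = tt.table.iloc[0]
        assert row["false_neg"] == 3
        assert row["true_pos"] == row["true_neg"] == row["false_pos"] == 0

    def test_counts_sum_to_n_at_every_threshold(self, preset):
        from integrotax.barcoding import k2p_matrix
        D = k2p_matrix(preset["sequences"])
        labels = [preset["species_of"][i] for i in D.labels]
        tt = optimize_threshold(D, labels)
        sums = tt.table[["true_pos", "true_neg", "false_pos",
                         "false_neg"]].sum(axis=1)
        assert (sums == len(D)).all()

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = int(rng.integers(4, 12))
            M = np.triu(rng.random((n, n)) * 0.1, 1)
            D = M + M.T
            labels = [f"g{rng.integers(0, 3)}" for _ in range(n)]
            dm = DistanceMatrix([f"i{k}" for k in range(n)], D)
            tt = optimize_threshold(dm, labels, [0.01, 0.05, 0.09])
            for _, row in tt.table.iterrows():
                oracle = brute_force_threshold_counts(D, labels, row["threshold"])
                for key, val in oracle.items():
                    assert row[key] == val

    def test_empty_grid_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, .1], [.1, 0.]]))
        with pytest.raises(ValueError):
            optimize_threshold(dm, ["x", "x"], [])

    def test_all_minimizers_reported_ascending(self):
        D = np.array([[0.0, 0.004, 0.06], [0.004, 0.0, 0.05], [0.06, 0.05, 0.0]])
        dm = DistanceMatrix(list("abc"), D)
        tt = optimize_threshold(dm, ["x", "x", "y"], [0.01, 0.02, 0.03])
        assert tt.optima == sorted(tt.optima)
        assert tt.optimum == tt.optima[0]
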