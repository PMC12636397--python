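"""Profiles, bit maps, distances, and complete-linkage clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdcoop import (
    complete_linkage,
    compute_bitmap,
    compute_profile,
    differential_bitmap,
    distance_matrix,
)
from hdcoop.constraints import MAX_BITS, DistanceMatrix
from hdcoop.sequences import CANONICAL_RESIDUES, RESIDUE_INDEX

from conftest import make_hd

LOG2_20 = math.log2(20)


def _random_seqs(rng, n):
    return [
        make_hd(
            f"r{i}",
            **{f"p{p}": CANONICAL_RESIDUES[rng.integers(20)] for p in range(1, 61)},
        )
        for i in range(n)
    ]


class TestProfile:
    def test_identical_sequences_give_degenerate_frequencies(self, compliant_seq):
        profile = compute_profile([compliant_seq] * 4)
        assert profile.n == 4
        freq = profile.frequencies
        assert np.all(freq.max(axis=1) == 1.0)
        assert freq[49, RESIDUE_INDEX["Q"]] == 1.0  # Q50

    def test_single_variable_position_counts(self):
        a, b = make_hd("a", p50="Q"), make_hd("b", p50="K")
        freq = compute_profile([a, b]).frequencies
        assert freq[49, RESIDUE_INDEX["Q"]] == 0.5
        assert freq[49, RESIDUE_INDEX["K"]] == 0.5
        mask = np.ones(60, dtype=bool)
        mask[49] = False
        assert np.all(freq[mask].max(axis=1) == 1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_profile([])


class TestBitMap:
    def test_fully_conserved_position_carries_log2_20_bits(self, compliant_seq):
        bm = compute_bitmap(compute_profile([compliant_seq] * 3))
        assert bm.ic == pytest.approx(np.full(60, LOG2_20))

    def test_uniform_position_carries_zero_bits(self):
        seqs = [make_hd(f"u{i}", p30=aa) for i, aa in enumerate(CANONICAL_RESIDUES)]
        bm = compute_bitmap(compute_profile(seqs))
        assert bm.ic[29] == pytest.approx(0.0, abs=1e-12)

    def test_two_residue_5050_split_loses_one_bit(self):
        bm = compute_bitmap(compute_profile([make_hd("a", p50="Q"), make_hd("b", p50="K")]))
        assert bm.ic[49] == pytest.approx(LOG2_20 - 1.0)

    def test_small_sample_correction_lowers_ic_and_clamps_at_zero(self):
        profile = compute_profile([make_hd("a"), make_hd("b", p30="V")])
        raw = compute_bitmap(profile, small_sample_correction=False)
        corrected = compute_bitmap(profile, small_sample_correction=True)
        assert np.all(corrected.ic <= raw.ic)
        assert np.all(corrected.ic >= 0.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_heights_normalize_to_ic_and_ic_is_bounded(self, seed):
        rng = np.random.default_rng(seed)
        bm = compute_bitmap(compute_profile(_random_seqs(rng, rng.integers(2, 8))))
        assert np.allclose(bm.heights.sum(axis=1), bm.ic, atol=1e-9)
        assert np.all((bm.ic >= 0.0) & (bm.ic <= MAX_BITS + 1e-12))

    def test_ic_invariant_to_order_and_duplication(self):
        seqs = [make_hd("a", p40="E"), make_hd("b", p40="K"), make_hd("c")]
        ic1 = compute_bitmap(compute_profile(seqs)).ic
        ic2 = compute_bitmap(compute_profile(seqs[::-1] + seqs[::-1])).ic
        assert np.allclose(ic1, ic2)


class TestDifferentialBitMap:
    def test_identical_maps_cancel(self, compliant_seq):
        bm = compute_bitmap(compute_profile([compliant_seq] * 2))
        assert np.all(differential_bitmap(bm, bm).delta == 0.0)

    def test_conserved_swap_at_one_position(self):
        pl = compute_bitmap(compute_profile([make_hd("p", p32="E")] * 3))
        antp = compute_bitmap(compute_profile([make_hd("q", p32="V")] * 3))
        delta = differential_bitmap(pl, antp).delta
        assert delta[31, RESIDUE_INDEX["E"]] == pytest.approx(LOG2_20)
        assert delta[31, RESIDUE_INDEX["V"]] == pytest.approx(-LOG2_20)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_family_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = compute_bitmap(compute_profile(_random_seqs(rng, 3)))
        b = compute_bitmap(compute_profile(_random_seqs(rng, 4)))
        assert np.allclose(
            differential_bitmap(a, b).delta, -differential_bitmap(b, a).delta
        )


class TestDistanceMatrix:
    def test_identical_sequences_are_at_distance_zero(self, compliant_seq):
        dm = distance_matrix([compliant_seq, make_hd("copy")])
        assert dm.d[0, 1] == 0.0

    def test_two_mismatches_give_distance_two(self):
        dm = distance_matrix([make_hd("a"), make_hd("b", p10="K", p20="E")])
        assert dm.d[0, 1] == pytest.approx(2.0)

    def test_maximally_different_sequences(self):
        a = make_hd("a")
        shifted = {
            f"p{p}": CANONICAL_RESIDUES[
                (RESIDUE_INDEX[a.residues[p - 1]] + 1) % 20
            ]
            for p in range(1, 61)
        }
        dm = distance_matrix([a, make_hd("b", **shifted)])
        assert dm.d[0, 1] == pytest.approx(math.sqrt(120))

    def test_fewer_than_two_sequences_rejected(self, compliant_seq):
        with pytest.raises(ValueError):
            distance_matrix([compliant_seq])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_distance_is_sqrt_2_hamming_by_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seqs = _random_seqs(rng, 5)
        dm = distance_matrix(seqs)
        for i in range(5):
            for j in range(5):
                hamming = sum(
                    x != y for x, y in zip(seqs[i].residues, seqs[j].residues)
                )
                assert dm.d[i, j] == pytest.approx(math.sqrt(2 * hamming))


class TestCompleteLinkage:
    def test_hand_computed_three_point_tree(self):
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        dendro = complete_linkage(DistanceMatrix(("A", "B", "C"), d))
        assert dendro.linkage[0][:3].tolist() == [0.0, 1.0, 1.0]
        assert dendro.linkage[1][2] == 10.0
        order = dendro.leaf_order()
        assert sorted(order) == ["A", "B", "C"]
        assert abs(order.index("A") - order.index("B")) == 1  # first merge stays adjacent

    def test_all_equal_distances_merge_lowest_pairs_first(self):
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        dendro = complete_linkage(DistanceMatrix(("A", "B", "C", "D"), d))
        assert np.all(dendro.merge_heights == 3.0)
        assert dendro.linkage[0][:2].tolist() == [0.0, 1.0]  # (A, B) first
        assert dendro.linkage[1][:2].tolist() == [2.0, 3.0]

    def test_merge_heights_are_monotone(self):
        rng = np.random.default_rng(11)
        seqs = _random_seqs(rng, 8)
        dendro = complete_linkage(distance_matrix(seqs))
        assert np.all(np.diff(dendro.merge_heights) >= 0.0)

    def test_agrees_with_scipy_on_tie_free_distances(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        n = 9
        d = squareform(rng.uniform(1.0, 9.0, size=n * (n - 1) // 2))
        dendro = complete_linkage(DistanceMatrix(tuple("abcdefghi"), d))
        z_ref = linkage(squareform(d), method="complete")
        assert np.allclose(
            cophenet(dendro.linkage), cophenet(z_ref), atol=1e-12
        )

    def test_non_finite_distances_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            complete_linkage(DistanceMatrix(("a", "b"), d))

    def test_two_cluster_cut_recovers_separated_synthetic_families(self):
        from hdcoop import SyntheticFamilyConfig, profile_from_consensus, simulate_family

        base = make_hd("base").residues
        other = list(base)
        for p in range(1, 13):  # distinct, fully conserved at 12 positions
            other[p * 4 - 1] = "W" if base[p * 4 - 1] != "W" else "Y"
        fam_a = simulate_family(
            SyntheticFamilyConfig(profile_from_consensus(base, 0.97), n=15,
                                  seed=5, family="PairedLike", id_prefix="pl")
        )
        fam_b = simulate_family(
            SyntheticFamilyConfig(profile_from_consensus("".join(other), 0.97),
                                  n=15, seed=6, family="ANTP", id_prefix="an")
        )
        dendro = complete_linkage(distance_matrix(fam_a + fam_b))
        cut = dendro.cut(2)
        labels_a = {cut[s.id] for s in fam_a}
        labels_b = {cut[s.id] for s in fam_b}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_newick_export_parses_and_preserves_leaves(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(7)
        seqs = _random_seqs(rng, 6)
        dendro = complete_linkage(distance_matrix(seqs))
        tree = Phylo.read(StringIO(dendro.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(
            s.id for s in seqs
        )
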