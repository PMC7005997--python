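import numpy as np
import pytest

from cladecompare.seqio import GeneAnnotation, reverse_complement
from cladecompare.synteny import (
    Breakpoint,
    SyntenyAnchor,
    breakpoints,
    cluster_anchors,
    find_anchors,
    mobilome_breakpoint_overlap,
)
from cladecompare.synthetic import CladeConfig, simulate_clade, _dna_str, _random_dna, jc_mutate

from oracles import mem_set


def _random_seq(n, seed):
    return _dna_str(_random_dna(n, 0.5, np.random.default_rng(seed)))


class TestFindAnchors:
    def test_self_identity_is_one_full_anchor(self):
        s = _random_seq(1000, 0)
        anchors = find_anchors(s, s, 20)
        full = [a for a in anchors if a.length == 1000]
        assert len(full) == 1
        a = full[0]
        assert (a.q_start, a.q_end, a.r_start, a.r_end) == (0, 1000, 0, 1000)
        assert a.orientation == "forward"

    def test_reverse_complement_is_one_reverse_anchor(self):
        s = _random_seq(1000, 1)
        anchors = find_anchors(s, reverse_complement(s), 20)
        full = [a for a in anchors if a.length == 1000]
        assert len(full) == 1
        assert full[0].orientation == "reverse"

    def test_planted_segment_found_exactly(self):
        rng = np.random.default_rng(2)
        segment = _dna_str(_random_dna(300, 0.5, rng))
        q = _random_seq(5000, 3)
        r = _random_seq(5000, 4)
        q = q[:1000] + segment + q[1300:]
        r = r[:3000] + segment + r[3300:]
        anchors = find_anchors(q, r, 50)
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.q_start, a.q_end, a.r_start, a.r_end) == (1000, 1300, 3000, 3300)
        assert anchors[0].verify(q, r)
        assert {(x.q_start, x.q_end, x.r_start, x.r_end, x.orientation)
                for x in anchors} == mem_set(q, r, 50)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            find_anchors("", "ACGT", 2)

    def test_matches_brute_force_on_diverged_pair(self):
        rng = np.random.default_rng(5)
        base = _random_dna(1500, 0.5, rng)
        q = _dna_str(base)
        r = _dna_str(jc_mutate(base, 0.05, rng))
        anchors = find_anchors(q, r, 20)
        assert len(anchors) > 5
        got = {(a.q_start, a.q_end, a.r_start, a.r_end, a.orientation) for a in anchors}
        assert got == mem_set(q, r, 20)
        assert all(a.verify(q, r) for a in anchors)

    def test_symmetry_under_query_ref_swap(self):
        rng = np.random.default_rng(6)
        base = _random_dna(1200, 0.5, rng)
        q = _dna_str(base)
        r = _dna_str(jc_mutate(base, 0.04, rng))
        fwd = {(a.q_start, a.q_end, a.r_start, a.r_end, a.orientation)
               for a in find_anchors(q, r, 20)}
        swapped = {(a.r_start, a.r_end, a.q_start, a.q_end, a.orientation)
                   for a in find_anchors(r, q, 20)}
        assert fwd == swapped


def _anchor(qs, qe, rs, re, orient="forward"):
    return SyntenyAnchor(qs, qe, rs, re, orient)


class TestClusterAnchors:
    def test_colinear_anchors_chain_into_one_block(self):
        a1 = _anchor(0, 150, 0, 150)
        a2 = _anchor(250, 400, 250, 400)
        blocks = cluster_anchors([a1, a2], min_cluster_len=200, max_gap=500)
        assert len(blocks) == 1
        assert blocks[0].anchored_length == 300

    def test_short_lone_anchor_discarded(self):
        blocks = cluster_anchors([_anchor(0, 150, 0, 150)], min_cluster_len=200)
        assert blocks == []

    def test_crossing_anchors_never_chain(self):
        a1 = _anchor(0, 250, 1000, 1250)
        a2 = _anchor(300, 550, 0, 250)  # reference jumps backwards
        blocks = cluster_anchors([a1, a2], min_cluster_len=200, max_gap=500)
        assert len(blocks) == 2

    def test_gap_larger_than_max_gap_splits_blocks(self):
        a1 = _anchor(0, 250, 0, 250)
        a2 = _anchor(1000, 1250, 1000, 1250)
        blocks = cluster_anchors([a1, a2], min_cluster_len=200, max_gap=500)
        assert len(blocks) == 2

    def test_opposite_orientations_never_chain(self):
        a1 = _anchor(0, 250, 0, 250, "forward")
        a2 = _anchor(300, 550, 300, 550, "reverse")
        blocks = cluster_anchors([a1, a2], min_cluster_len=200)
        assert len(blocks) == 2
        assert {b.orientation for b in blocks} == {"forward", "reverse"}


class TestBreakpoints:
    def test_single_block_has_no_breakpoints(self):
        blocks = cluster_anchors([_anchor(0, 500, 0, 500)], min_cluster_len=200)
        assert breakpoints(blocks, 500) == []

    def test_orientation_flip_is_flagged_inversion(self):
        blocks = cluster_anchors(
            [_anchor(0, 500, 0, 500, "forward"), _anchor(600, 1100, 600, 1100, "reverse")],
            min_cluster_len=200,
        )
        bps = breakpoints(blocks, 1100)
        assert len(bps) == 1
        assert bps[0].is_inversion
        assert bps[0].position == 500

    def test_planted_inversions_yield_flip_breakpoints_at_boundaries(self):
        cfg = CladeConfig(
            tree="((A:0.001,B:0.001):0.001,C:0.02)root;",
            outgroup="C",
            genome_length=60_000,
            n_gene_families=40,
            mean_gene_len=600,
            hgt_rate=0.0,
            is_element=(500, {}),
            n_inversions={"B": 2},
            seed=5,
        )
        genomes, truth, _ = simulate_clade(cfg)
        by = {g.genome_id: g for g in genomes}
        inv = truth.inversions[truth.inversions.genome_id == "B"]
        assert len(inv) == 2
        anchors = find_anchors(by["B"].sequence, by["A"].sequence, 30)
        blocks = cluster_anchors(anchors, min_cluster_len=200, max_gap=500)
        bps = breakpoints(blocks, len(by["B"].sequence))
        flips = [bp.position for bp in bps if bp.is_inversion]
        tol = 600  # max_gap plus local anchor loss at junctions
        for boundary in sorted(set(inv["start"]) | set(inv["end"])):
            assert any(abs(boundary - p) <= tol for p in flips), boundary


class TestMobilomeOverlap:
    def _bps(self, positions):
        return [Breakpoint(p, "forward", "reverse") for p in positions]

    def _mob(self, intervals):
        return [
            GeneAnnotation(f"is{i}", s, e, "+", "mobile_element")
            for i, (s, e) in enumerate(intervals)
        ]

    def test_no_mobilome_is_undefined_with_zero_fraction(self):
        res = mobilome_breakpoint_overlap(self._bps([100]), [], 10_000)
        assert not res.defined
        assert res.observed_fraction == 0.0

    def test_features_at_breakpoints_give_full_overlap(self):
        bps = self._bps([10_000, 20_000, 30_000])
        mob = self._mob([(9_900, 10_100), (19_900, 20_100), (29_900, 30_100)])
        res = mobilome_breakpoint_overlap(bps, mob, 100_000, margin=500,
                                          n_perm=200, seed=0)
        assert res.observed_fraction == 1.0
        assert res.p_value < 0.05

    def test_independent_placement_is_not_significant(self):
        rng = np.random.default_rng(7)
        L = 200_000
        bps = self._bps(sorted(rng.integers(0, L, 8)))
        mob = self._mob([(int(s), int(s) + 800) for s in rng.integers(0, L - 800, 5)])
        res = mobilome_breakpoint_overlap(bps, mob, L, margin=2000, n_perm=500, seed=1)
        assert res.defined
        assert res.p_value > 0.01
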