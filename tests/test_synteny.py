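"""Collinear chaining, fusion/translocation calls, projection, overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_anchor_frame
from karyoshift import simdata, synteny
from karyoshift.genome_io import Interval
from karyoshift.synteny import (
    ChainParams, chain_blocks, chain_indices, detect_fusions,
    detect_translocations, inversion_overlap, project_interval, rank_anchors,
    swap_anchor_table,
)


def brute_force_best_chain_len(perm, max_gap):
    """Independent oracle: longest collinear subsequence (either sign) with
    both rank gaps bounded, by quadratic dynamic programming."""
    n = len(perm)
    best = 1 if n else 0
    for sign in (1, -1):
        L = [1] * n
        for j in range(n):
            for i in range(max(0, j - max_gap), j):
                d = (perm[j] - perm[i]) * sign
                if 1 <= d <= max_gap and L[i] + 1 > L[j]:
                    L[j] = L[i] + 1
            best = max(best, L[j])
    return best


def exhaustive_best_chain_len(perm, max_gap):
    """Subset-enumeration cross-check of the DP oracle (tiny n only)."""
    n = len(perm)
    best = 0
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        ok = True
        for a, b in zip(idx, idx[1:]):
            if b - a > max_gap or not (1 <= abs(perm[b] - perm[a]) <= max_gap):
                ok = False
                break
        if ok and len(idx) >= 2:
            d = [perm[b] - perm[a] for a, b in zip(idx, idx[1:])]
            ok = all(x > 0 for x in d) or all(x < 0 for x in d)
        best = max(best, len(idx)) if ok else best
    return best


def check_chain_invariants(chains, perm, max_gap, min_anchors):
    seen = set()
    for c in chains:
        assert len(c) >= min_anchors
        assert not (set(c) & seen), "anchor in more than one block"
        seen |= set(c)
        rr = [perm[i] for i in c]
        d = np.diff(rr)
        assert all(1 <= x <= max_gap for x in d) or all(1 <= -x <= max_gap for x in d)
        assert max(np.diff(sorted(c))) <= max_gap if len(c) > 1 else True


class TestChaining:
    def test_identity_order_single_forward_block(self):
        df = make_anchor_frame(range(10))
        (block,) = chain_blocks(df, ChainParams(10, 5))
        assert block.orientation == "forward" and block.n == 10

    def test_embedded_reversal_gives_three_blocks(self):
        """30 collinear anchors with ranks 11-20 reversed split into
        forward(10), reverse(10), forward(10)."""
        perm = list(range(10)) + list(range(19, 9, -1)) + list(range(20, 30))
        blocks = chain_blocks(make_anchor_frame(perm), ChainParams(10, 5))
        assert [(b.orientation, b.n) for b in blocks] == [
            ("forward", 10), ("reverse", 10), ("forward", 10)]

    def test_query_rank_gap_beyond_max_splits(self):
        """A same-reference pair separated by 11 intervening query ranks
        (filled by anchors to another chromosome) cannot share a chain."""
        rows = []
        for i in range(6):  # r1 genes, then an 11-gene r2 insert, then r1 again
            rows.append({"gene": f"a{i}", "qchrom": "q", "qstart": i * 1000,
                         "qend": i * 1000 + 10, "rchrom": "r1",
                         "rstart": i * 1000, "rend": i * 1000 + 10})
        for i in range(11):
            rows.append({"gene": f"x{i}", "qchrom": "q", "qstart": 6000 + i * 1000,
                         "qend": 6000 + i * 1000 + 10, "rchrom": "r2",
                         "rstart": i * 1000, "rend": i * 1000 + 10})
        for i in range(6):
            rows.append({"gene": f"b{i}", "qchrom": "q", "qstart": 17_000 + i * 1000,
                         "qend": 17_000 + i * 1000 + 10, "rchrom": "r1",
                         "rstart": 6000 + i * 1000, "rend": 6000 + i * 1000 + 10})
        blocks = chain_blocks(rank_anchors(pd.DataFrame(rows)), ChainParams(10, 5))
        r1_blocks = [b for b in blocks if b.rchrom == "r1"]
        assert sorted(b.n for b in r1_blocks) == [6, 6]

    def test_duplicate_gene_ids_rejected(self):
        df = make_anchor_frame(range(5))
        df.loc[1, "gene"] = df.loc[0, "gene"]
        with pytest.raises(ValueError, match="duplicate"):
            chain_blocks(df)

    def test_exhaustive_small_permutations_against_dp_oracle(self):
        """All permutations of up to 7 anchors: block invariants hold and
        kept chains cover at least the single best collinear chain."""
        max_gap, min_anchors = 3, 2
        for n in range(1, 8):
            for perm in itertools.permutations(range(n)):
                q = np.arange(n)
                r = np.array(perm)
                rch = np.array(["r"] * n)
                chains = chain_indices(q, r, rch, ChainParams(max_gap, min_anchors))
                check_chain_invariants(chains, perm, max_gap, min_anchors)
                best = brute_force_best_chain_len(perm, max_gap)
                if best >= min_anchors:
                    assert sum(len(c) for c in chains) >= best, perm

    def test_dp_oracle_agrees_with_subset_enumeration(self):
        for perm in itertools.permutations(range(5)):
            assert (brute_force_best_chain_len(perm, 2)
                    == exhaustive_best_chain_len(perm, 2)), perm

    def test_random_instances_against_dp_oracle(self, rng):
        max_gap, min_anchors = 4, 3
        for _ in range(200):
            perm = rng.permutation(15)
            chains = chain_indices(np.arange(15), perm, np.array(["r"] * 15),
                                   ChainParams(max_gap, min_anchors))
            check_chain_invariants(chains, perm, max_gap, min_anchors)
            best = brute_force_best_chain_len(list(perm), max_gap)
            if best >= min_anchors:
                assert sum(len(c) for c in chains) >= best

    def test_swap_symmetry_on_rearranged_genomes(self):
        """Swapping query and reference maps forward blocks to forward,
        reverse to reverse, with identical anchor sets."""
        cfg = simdata.SimConfig(
            seed=8,
            chromosomes=[("a1", 20_000_000), ("a2", 15_000_000)],
            inversions=[simdata.PlantedInversion("a1", 5_000_000, 12_000_000)],
        )
        anchors, _ = simdata.simulate_anchor_table(cfg)
        fwd = chain_blocks(rank_anchors(anchors))
        rev = chain_blocks(swap_anchor_table(anchors))
        key = lambda blocks: sorted(
            (b.orientation, frozenset(b.genes)) for b in blocks)
        assert key(fwd) == key(rev)


class TestFusions:
    def test_one_to_one_map_no_fusion(self):
        cfg = simdata.SimConfig(seed=1, chromosomes=[("a", 10_000_000), ("b", 10_000_000)])
        anchors, _ = simdata.simulate_anchor_table(cfg)
        blocks = chain_blocks(rank_anchors(anchors))
        assert detect_fusions(blocks) == []

    def test_planted_fusion_recovered_with_junction(self):
        cfg = simdata.SimConfig(
            seed=2, chromosomes=[("chrA", 10_000_000), ("chrB", 8_000_000)],
            fusions=[simdata.Fusion(("chrA", "chrB"), "fused")])
        anchors, truth = simdata.simulate_anchor_table(cfg)
        # concatenation arithmetic: derived chromosome is 18 Mb
        assert truth.derived_genome["fused"] == 18_000_000
        a = anchors[anchors["qchrom"] == "fused"].sort_values("qstart")
        assert list(dict.fromkeys(a["rchrom"])) == ["chrA", "chrB"]
        blocks = chain_blocks(rank_anchors(anchors))
        (call,) = detect_fusions(blocks)
        assert {p[0] for p in call.partners} == {"chrA", "chrB"}
        spacing = truth.anchor_spacing["fused"]
        assert abs(call.junctions[0] - truth.fusions[0]["junctions"][0]) <= spacing

    def test_fusion_with_small_central_translocation_keeps_two_partners(self):
        """A fused chromosome with a small embedded segment from a third
        chromosome still reports exactly the two major partners."""
        cfg = simdata.SimConfig(
            seed=3,
            chromosomes=[("A", 20_000_000), ("B", 16_000_000), ("C", 18_000_000)],
            fusions=[simdata.Fusion(("A", "B"), "fused")],
            translocations=[simdata.Translocation("C", 16_000_000, 18_000_000,
                                                  "fused", 19_000_000)])
        anchors, truth = simdata.simulate_anchor_table(cfg)
        blocks = chain_blocks(rank_anchors(anchors))
        calls = [c for c in detect_fusions(blocks) if c.qchrom == "fused"]
        assert len(calls) == 1
        assert {p[0] for p in calls[0].partners} == {"A", "B"}


class TestTranslocations:
    def test_no_minority_blocks_empty(self):
        cfg = simdata.SimConfig(seed=4, chromosomes=[("a", 10_000_000)])
        anchors, _ = simdata.simulate_anchor_table(cfg)
        assert detect_translocations(chain_blocks(rank_anchors(anchors))) == []

    def test_planted_internal_segment_recovered(self):
        cfg = simdata.SimConfig(
            seed=5, chromosomes=[("A", 20_000_000), ("C", 18_000_000)],
            translocations=[simdata.Translocation("C", 8_000_000, 10_000_000,
                                                  "A", 9_500_000)])
        anchors, truth = simdata.simulate_anchor_table(cfg)
        blocks = chain_blocks(rank_anchors(anchors))
        segs = [t for t in detect_translocations(blocks) if t.qchrom == "A"]
        assert len(segs) == 1
        t = segs[0]
        spacing = truth.anchor_spacing["A"]
        assert t.source_rchrom == "C" and not t.terminal
        assert abs(t.qstart - 9_500_000) <= spacing
        assert abs(t.qend - 11_500_000) <= spacing + 1000

    def test_terminal_segment_flagged(self):
        cfg = simdata.SimConfig(
            seed=6, chromosomes=[("A", 20_000_000), ("C", 18_000_000)],
            translocations=[simdata.Translocation("C", 8_000_000, 10_000_000,
                                                  "A", 19_100_000)])
        anchors, _ = simdata.simulate_anchor_table(cfg)
        segs = [t for t in detect_translocations(chain_blocks(rank_anchors(anchors)))
                if t.qchrom == "A" and t.source_rchrom == "C"]
        assert len(segs) == 1 and segs[0].terminal


class TestProjection:
    def setup_method(self):
        self.df = make_anchor_frame(range(100), spacing=10_000)
        self.blocks = chain_blocks(self.df, ChainParams(10, 5))

    def test_block_span_projects_to_reference_span(self):
        (b,) = self.blocks
        out = project_interval(self.blocks, Interval("q1", b.qstart, b.qend))
        assert out == [Interval("q1", b.rstart, b.rend)] or (
            out[0].chrom == "r1" and out[0].start == b.rstart and out[0].end == b.rend)

    def test_midpoint_interpolates_within_anchor_spacing(self):
        (b,) = self.blocks
        mid = (b.qstart + b.qend) // 2
        (out,) = project_interval(self.blocks, Interval("q1", mid, mid + 1))
        ref_mid = (b.rstart + b.rend) // 2
        assert abs(out.start - ref_mid) <= 10_000 // 2 + 1

    def test_reverse_block_swaps_endpoints(self):
        perm = list(range(49, -1, -1))
        blocks = chain_blocks(make_anchor_frame(perm, spacing=10_000),
                              ChainParams(10, 5))
        (b,) = blocks
        assert b.orientation == "reverse"
        lo = project_interval(blocks, Interval("q1", b.qstart, b.qstart + 1))
        hi = project_interval(blocks, Interval("q1", b.qend - 1, b.qend))
        assert lo[0].start > hi[0].start  # query start maps near reference end

    def test_unmapped_interval_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            out = project_interval(self.blocks, Interval("qX", 0, 100))
        assert out == [] and "no synteny block" in caplog.text


class TestInversionOverlap:
    def test_identity_map_full_overlap_and_flags(self):
        blocks = chain_blocks(make_anchor_frame(range(200), spacing=10_000),
                              ChainParams(10, 5))
        inv = Interval("q1", 300_000, 1_200_000, "inv")
        call = inversion_overlap(inv, Interval("r1", 300_000, 1_200_000, "inv_b"),
                                 blocks)
        assert call.frac_a == pytest.approx(1.0, abs=0.02)
        assert call.frac_b == pytest.approx(1.0, abs=0.02)
        assert call.partly_overlapping
        assert call.breakpoint_start and call.breakpoint_end

    def test_disjoint_projection_no_overlap(self):
        blocks = chain_blocks(make_anchor_frame(range(200), spacing=10_000),
                              ChainParams(10, 5))
        call = inversion_overlap(Interval("q1", 100_000, 400_000, "a"),
                                 Interval("r1", 1_000_000, 1_500_000, "b"), blocks)
        assert call.overlap_bp == 0 and not call.partly_overlapping

    def test_planted_partial_overlap_single_breakpoint_flag(self):
        """Inversion A's end lies inside B; the shared start breakpoints are
        within one flank, the ends far apart: exactly one flag."""
        cfg = simdata.SimConfig(
            seed=7, chromosomes=[("c", 30_000_000)], genes_per_mb=40.0,
            inversions=[simdata.PlantedInversion("c", 8_000_000, 14_000_000)])
        anchors, truth = simdata.simulate_anchor_table(cfg)
        blocks = chain_blocks(rank_anchors(anchors))
        inv_a = truth.inversions[0]
        inv_b = Interval("c", 8_030_000, 17_000_000, "inv_b")  # reference coords
        call = inversion_overlap(inv_a, inv_b, blocks)
        spacing = truth.anchor_spacing["c"]
        planted_overlap = 14_000_000 - 8_030_000
        assert abs(call.overlap_bp - planted_overlap) <= 2 * spacing
        assert call.partly_overlapping
        assert call.breakpoint_start != call.breakpoint_end
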