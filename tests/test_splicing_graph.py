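"""Locus clustering, splicing-graph construction, repair, and correction."""

from __future__ import annotations

import numpy as np
import pytest

import splicecomb as sc
from splicecomb.splicing_graph import Fragment

from conftest import graph_from_parts, make_alignment, parse_sam_fragments


class TestClusterLoci:
    def test_overlapping_reads_share_a_locus(self):
        reads = [
            make_alignment("c", [(100, 150)], "a"),
            make_alignment("c", [(149, 200)], "b"),
        ]
        assert len(sc.cluster_loci(reads)) == 1

    def test_distant_mates_share_a_locus(self):
        reads = [
            make_alignment("c", [(100, 150)], "p", mate=True, is_read1=True),
            make_alignment("c", [(10100, 10150)], "p", mate=True, is_read1=False),
        ]
        assert len(sc.cluster_loci(reads)) == 1

    def test_disjoint_islands_form_separate_loci(self):
        reads = [
            make_alignment("c", [(100, 150)], "a"),
            make_alignment("c", [(5000, 5050)], "b"),
            make_alignment("c", [(9000, 9050)], "d"),
        ]
        assert len(sc.cluster_loci(reads)) == 3

    def test_micro_gap_merges_islands(self):
        reads = [
            make_alignment("c", [(100, 150)], "a"),
            make_alignment("c", [(180, 230)], "b"),  # 30 bp gap < max_gap
        ]
        assert len(sc.cluster_loci(reads, max_gap=50)) == 1
        assert len(sc.cluster_loci(reads, max_gap=10)) == 2

    def test_shared_junction_clusters_regardless_of_gap(self):
        reads = [
            make_alignment("c", [(100, 150), (5000, 5050)], "a"),
            make_alignment("c", [(5040, 5090)], "b"),
        ]
        assert len(sc.cluster_loci(reads)) == 1

    def test_conflicting_strands_split(self):
        reads = [
            make_alignment("c", [(100, 200), (300, 400)], "a", strand="+"),
            make_alignment("c", [(150, 250), (350, 450)], "b", strand="-"),
            make_alignment("c", [(120, 180)], "u", strand="?"),
        ]
        loci = sc.cluster_loci(reads)
        assert sorted(l.strand for l in loci) == ["+", "-"]
        # the untagged read joins both strand loci
        assert all(any(a.read_id == "u" for a in l.reads) for l in loci)


class TestBuildGraph:
    def test_two_exon_locus(self, two_exon_locus):
        g = sc.build_graph(two_exon_locus)
        assert len(g.nodes) == 2
        assert [e.key for e in g.edges] == [(150, 250)]
        assert g.edges[0].coverage == 7

    def test_skipped_exon_topology(self):
        reads = []
        for i in range(4):
            reads.append(make_alignment("c", [(90 + i, 100), (200, 210 + i)], f"ab{i}"))
            reads.append(make_alignment("c", [(290 + i, 300), (400, 410 + i)], f"bc{i}"))
            reads.append(make_alignment("c", [(90 + i, 100), (400, 410 + i)], f"ac{i}"))
        for s in range(200, 271, 10):  # cover exon B contiguously to its donor
            reads.append(make_alignment("c", [(s, s + 30)], f"fill{s}"))
        g = sc.build_graph(sc.LocusReads("c", "+", reads))
        assert len(g.nodes) == 3
        assert {e.key for e in g.edges} == {(100, 200), (300, 400), (100, 400)}

    def test_min_junction_reads_floor(self, two_exon_locus):
        cfg = sc.AssemblyConfig(min_junction_reads=8)
        g = sc.build_graph(two_exon_locus, config=cfg)
        assert g.edges == []

    def test_edge_coverage_invariant_under_read_order(self, two_exon_locus):
        import random

        g1 = sc.build_graph(two_exon_locus)
        shuffled = list(two_exon_locus.reads)
        random.Random(3).shuffle(shuffled)
        g2 = sc.build_graph(sc.LocusReads("chrT", "+", shuffled))
        assert [(e.key, e.coverage) for e in g1.edges] == [
            (e.key, e.coverage) for e in g2.edges
        ]
        assert [n.interval for n in g1.nodes] == [n.interval for n in g2.nodes]

    def test_edge_coverage_sums_to_junction_incidences(self):
        loci = sc.recovery_suite(11, n_loci=3)
        sam, _, _ = sc.simulate_dataset(loci, "/tmp/sc_sum", seed=11)
        (_, reads), = sc.read_alignments(sam)
        incidences = sum(len(a.blocks) - 1 for a in reads)
        total = 0
        for locus in sc.cluster_loci(reads):
            g = sc.build_graph(locus)
            total += sum(e.coverage for e in g.edges)
        assert total == incidences


def test_pair_support_matches_brute_force(tmp_path):
    """pair_support equals an exhaustive count over the raw fragment list."""
    locus = sc.SimLocus(
        ref_name="chrP",
        ref_length=10000,
        exons=[(1000, 1200), (1400, 1500), (1700, 1800), (2100, 2300)],
        isoforms=[[0, 1, 2, 3], [0, 2, 3]],
        abundances=[30.0, 10.0],
        n_fragments=400,
        seed=3,
    )
    sam, _, _ = sc.simulate_dataset([locus], str(tmp_path), seed=3)
    (_, reads), = sc.read_alignments(sam)
    (locus_reads,) = sc.cluster_loci(reads)
    g = sc.build_graph(locus_reads)

    # oracle: re-parse the SAM text, enumerate fragments, count pairs of
    # junctions spanned by the same fragment for each shared-exon pair
    frags = parse_sam_fragments(open(sam))
    edge_keys = {e.key for e in g.edges}
    shared = {}  # (k1,k2) -> True when k1's acceptor-node ends at k2's donor
    starts = {n.start: n for n in g.nodes}
    for k1 in edge_keys:
        for k2 in edge_keys:
            n = starts.get(k1[1])
            if n is not None and n.end == k2[0]:
                shared[(k1, k2)] = True
    expected = {}
    for blocks_per_read in frags.values():
        spanned = set()
        for blocks in blocks_per_read:
            for i in range(len(blocks) - 1):
                spanned.add((blocks[i][1], blocks[i + 1][0]))
        spanned &= edge_keys
        for k1 in spanned:
            for k2 in spanned:
                if (k1, k2) in shared:
                    expected[(k1, k2)] = expected.get((k1, k2), 0) + 1
    assert g.pair_support == expected
    assert expected, "fixture must actually exercise pair support"


class TestRepairFragmentedExons:
    def _gap_graph(self, n_pairs, cov=10):
        g = graph_from_parts([(0, 80), (120, 200)], {}, coverage=cov)
        frags = [
            Fragment((((0, 50),), ((150, 200),)), ()) for _ in range(n_pairs)
        ]
        g.fragments = frags
        return g

    def test_supported_gap_is_filled(self):
        g = sc.repair_fragmented_exons(self._gap_graph(3), max_fill=300, min_pairs=2)
        assert [n.interval for n in g.nodes] == [(0, 200)]
        assert g.cov[100] == 10  # mean of equal flanks

    def test_insufficient_pairs_leave_gap(self):
        g = sc.repair_fragmented_exons(self._gap_graph(1), max_fill=300, min_pairs=2)
        assert [n.interval for n in g.nodes] == [(0, 80), (120, 200)]

    def test_gap_wider_than_max_fill_untouched(self):
        g = sc.repair_fragmented_exons(self._gap_graph(5), max_fill=30, min_pairs=2)
        assert len(g.nodes) == 2

    def test_junction_spanning_gap_blocks_merge(self):
        g = graph_from_parts([(0, 80), (120, 200)], {(80, 120): 5}, coverage=10)
        g.fragments = [Fragment((((0, 50),), ((150, 200),)), ()) for _ in range(5)]
        out = sc.repair_fragmented_exons(g, max_fill=300, min_pairs=2)
        assert len(out.nodes) == 2  # the gap is a real intron

    def test_transitive_merge_and_idempotence(self):
        g = graph_from_parts([(0, 80), (120, 200), (240, 320)], {}, coverage=10)
        g.fragments = [
            Fragment((((0, 60),), ((130, 190),)), ()),
            Fragment((((10, 70),), ((125, 195),)), ()),
            Fragment((((130, 190),), ((250, 310),)), ()),
            Fragment((((140, 195),), ((245, 300),)), ()),
        ]
        r1 = sc.repair_fragmented_exons(g, max_fill=300, min_pairs=2)
        assert [n.interval for n in r1.nodes] == [(0, 320)]
        r2 = sc.repair_fragmented_exons(r1, max_fill=300, min_pairs=2)
        assert [n.interval for n in r2.nodes] == [(0, 320)]
        assert np.array_equal(r1.cov, r2.cov)


class TestSplitPseudoExons:
    def test_uniform_node_unchanged(self):
        g = graph_from_parts([(0, 600)], {}, coverage=50)
        out = sc.split_pseudo_exons(g, window=50, drop_ratio=0.1)
        assert [n.interval for n in out.nodes] == [(0, 600)]

    def test_low_middle_splits_node_exactly(self):
        g = graph_from_parts([(0, 600)], {}, coverage=50)
        g.cov[200:400] = 2
        g._invalidate()
        out = sc.split_pseudo_exons(g, window=50, drop_ratio=0.1)
        assert [n.interval for n in out.nodes] == [(0, 200), (400, 600)]

    def test_terminal_low_run_trimmed_not_split(self):
        g = graph_from_parts([(0, 600)], {}, coverage=50)
        g.cov[0:100] = 2
        g._invalidate()
        out = sc.split_pseudo_exons(g, window=50, drop_ratio=0.1)
        assert [n.interval for n in out.nodes] == [(100, 600)]

    def test_junction_anchored_end_never_trimmed(self):
        # low run at the node start, but an in-junction lands exactly there
        g = graph_from_parts(
            [(0, 100), (200, 800)], {(100, 200): 4}, coverage=[4, 50]
        )
        g.cov[200 - g.offset : 300 - g.offset] = 4
        g._invalidate()
        out = sc.split_pseudo_exons(g, window=50, drop_ratio=0.1)
        assert (200, 800) in [n.interval for n in out.nodes]

    def test_unattached_intronic_node_discarded(self):
        # exon--intron(noise)--exon with junction boundaries at donor/acceptor
        g = graph_from_parts(
            [(0, 200), (200, 500), (500, 700)],
            {(200, 500): 40},
            coverage=[50, 3, 50],
        )
        out = sc.split_pseudo_exons(g, window=50, drop_ratio=0.1)
        assert [n.interval for n in out.nodes] == [(0, 200), (500, 700)]
        assert {e.key for e in out.edges} == {(200, 500)}

    def test_idempotent(self):
        g = graph_from_parts([(0, 600)], {}, coverage=50)
        g.cov[250:380] = 1
        g.cov[0:60] = 2
        g._invalidate()
        s1 = sc.split_pseudo_exons(g)
        s2 = sc.split_pseudo_exons(s1)
        assert np.array_equal(s1.cov, s2.cov)
        assert [n.interval for n in s1.nodes] == [n.interval for n in s2.nodes]


def test_noise_free_graph_matches_truth_boundaries(tmp_path):
    """Deep noise-free coverage yields exactly the true junction structure."""
    locus = sc.SimLocus(
        ref_name="chrB",
        ref_length=10000,
        exons=[(1000, 1250), (1450, 1560), (1800, 1930), (2200, 2450)],
        isoforms=[[0, 1, 2, 3], [0, 2, 3]],
        abundances=[100.0, 30.0],
        n_fragments=600,
        seed=9,
    )
    sam, _, _ = sc.simulate_dataset([locus], str(tmp_path), seed=9)
    (_, reads), = sc.read_alignments(sam)
    (lr,) = sc.cluster_loci(reads)
    g = sc.split_pseudo_exons(sc.repair_fragmented_exons(sc.build_graph(lr)))
    truth_junctions = {(1250, 1450), (1560, 1800), (1930, 2200), (1250, 1800)}
    assert {e.key for e in g.edges} == truth_junctions
    # every internal (junction-side) boundary is exact; terminal ends are
    # coverage-limited and may fall within a read length of the truth
    bounds = {n.start for n in g.nodes} | {n.end for n in g.nodes}
    for d, a in truth_junctions:
        assert d in bounds and a in bounds
    assert abs(min(bounds) - 1000) < 100 and abs(max(bounds) - 2450) < 100
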