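"""Junction-graph construction, bin-packing weighting, mate promotion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splicecomb as sc

from conftest import brute_force_binpack, graph_from_parts

# a 4-exon skeleton used by several structural tests
EXONS4 = [(0, 100), (200, 300), (400, 500), (600, 700)]


class TestBuildJunctionGraph:
    def test_linear_chain(self):
        g = graph_from_parts(EXONS4[:3], {(100, 200): 5, (300, 400): 7})
        jg = sc.build_junction_graph(g)
        assert jg.node_weight == {(100, 200): 5, (300, 400): 7}
        assert set(jg.edge_weight) == {((100, 200), (300, 400))}
        assert all(w == 0 for w in jg.edge_weight.values())

    def test_incidence_only_at_shared_exons(self):
        # edges: 1 = A->B, 2 = B->C, 3 = A->C; 1-2 incident, 1-3 not
        g = graph_from_parts(
            EXONS4[:3], {(100, 200): 5, (300, 400): 7, (100, 400): 3}
        )
        jg = sc.build_junction_graph(g)
        assert set(jg.edge_weight) == {((100, 200), (300, 400))}

    def test_diamond_two_in_two_out(self):
        # two alternative donors into a shared exon, two alternative acceptors out
        exons = [(0, 100), (120, 220), (300, 400), (500, 600), (620, 720)]
        juncs = {(100, 300): 9, (220, 300): 8, (400, 500): 9, (400, 620): 8}
        g = graph_from_parts(exons, juncs)
        jg = sc.build_junction_graph(g)
        assert len(jg.node_weight) == 4
        assert len(jg.edge_weight) == 4

    def test_empty_graph(self):
        g = graph_from_parts([(0, 300)], {})
        jg = sc.build_junction_graph(g)
        assert jg.node_weight == {} and jg.edge_weight == {}


class TestSolveBinpacking:
    @pytest.mark.parametrize(
        "items,bins,expected_assignment,expected_z",
        [
            ([10], [10], [0], 0),
            ([30, 10], [28, 12], [0, 1], 8),  # alternative costs 648
            ([20, 20, 5], [25, 20], [0, 1, 0], 0),
        ],
    )
    def test_worked_examples(self, items, bins, expected_assignment, expected_z):
        inst = sc.solve_binpacking(sc.BinPackingInstance(items, bins), "exact")
        assert inst.assignment == expected_assignment
        assert inst.z == expected_z

    def test_role_contract_violation(self):
        with pytest.raises(ValueError):
            sc.solve_binpacking(sc.BinPackingInstance([5], [3, 2]), "exact")

    def test_partitionable_instance_reaches_zero(self):
        items, bins = [9, 7, 5, 3, 1], [16, 9]
        inst = sc.solve_binpacking(sc.BinPackingInstance(items, bins), "exact")
        assert inst.z == 0

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_exact_matches_enumeration(self, data):
        m = data.draw(st.integers(1, 4))
        n = data.draw(st.integers(m, 6))
        items = data.draw(st.lists(st.integers(1, 50), min_size=n, max_size=n))
        bins = data.draw(st.lists(st.integers(1, 50), min_size=m, max_size=m))
        inst = sc.solve_binpacking(sc.BinPackingInstance(items, bins), "exact")
        assert inst.z == brute_force_binpack(items, bins)
        assert sorted(set(inst.assignment)) == list(range(m))  # surjective

    def test_heuristic_feasible_and_at_most_first_fit(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(m, 9))
            items = [int(x) for x in rng.integers(1, 51, n)]
            bins = [int(x) for x in rng.integers(1, 51, m)]
            inst = sc.solve_binpacking(sc.BinPackingInstance(items, bins), "heuristic")
            assert sorted(set(inst.assignment)) == list(range(m))
            # size-ordered first fit: items descending into first bin with room,
            # else the emptiest bin; surjectivity enforced at the tail
            order = sorted(range(n), key=lambda j: -items[j])
            loads, assign = [0] * m, {}
            for idx, j in enumerate(order):
                empty = [i for i in range(m) if loads[i] == 0]
                if empty and len(empty) == n - idx:
                    i = empty[0]
                else:
                    fits = [i for i in range(m) if loads[i] + items[j] <= bins[i]]
                    i = fits[0] if fits else min(range(m), key=lambda i: loads[i])
                loads[i] += items[j]
                assign[j] = i
            ff_z = sum(
                (c - l) ** 2 for c, l in zip(bins, loads)
            )
            assert inst.z <= ff_z


class TestWeightEdges:
    def _weighted(self, exons, juncs):
        g = graph_from_parts(exons, juncs)
        jg = sc.build_junction_graph(g)
        return sc.weight_edges_binpacking(jg, g), g

    def test_single_in_single_out(self):
        jg, _ = self._weighted(EXONS4[:3], {(100, 200): 5, (300, 400): 7})
        assert jg.edge_weight[((100, 200), (300, 400))] == 1

    def test_coverage_matched_pairing(self):
        exons = [(0, 100), (120, 220), (300, 400), (500, 600), (620, 720)]
        juncs = {(100, 300): 30, (220, 300): 10, (400, 500): 28, (400, 620): 12}
        jg, _ = self._weighted(exons, juncs)
        assert jg.edge_weight[((100, 300), (400, 500))] == 1
        assert jg.edge_weight[((220, 300), (400, 620))] == 1
        assert jg.edge_weight[((100, 300), (400, 620))] == 0
        assert jg.edge_weight[((220, 300), (400, 500))] == 0

    def test_degenerate_tie_break_is_deterministic(self):
        exons = [(0, 100), (120, 220), (300, 400), (500, 600), (620, 720)]
        juncs = {(100, 300): 20, (220, 300): 20, (400, 500): 20, (400, 620): 20}
        jg, _ = self._weighted(exons, juncs)
        ones = {pair for pair, w in jg.edge_weight.items() if w == 1}
        # both matchings give z=0; coordinate order picks the parallel one
        assert ones == {
            ((100, 300), (400, 500)),
            ((220, 300), (400, 620)),
        }

    def test_role_swap_more_outs_than_ins(self):
        # one in-junction feeding two alternative out-junctions
        exons = [(0, 100), (200, 300), (400, 500), (600, 700)]
        juncs = {(100, 200): 40, (300, 400): 30, (300, 600): 10}
        jg, _ = self._weighted(exons, juncs)
        assert jg.edge_weight[((100, 200), (300, 400))] == 1
        assert jg.edge_weight[((100, 200), (300, 600))] == 1


class TestPromotePairedEdges:
    def _setup(self, support, promote_zero=True):
        exons = [(0, 100), (120, 220), (300, 400), (500, 600), (620, 720)]
        juncs = {(100, 300): 30, (220, 300): 10, (400, 500): 28, (400, 620): 12}
        g = graph_from_parts(exons, juncs, pair_support=support)
        jg = sc.weight_edges_binpacking(sc.build_junction_graph(g), g)
        return sc.promote_paired_edges(jg, g, min_pairs=2, promote_zero_weight=promote_zero), g

    def test_promotes_zero_weight_edge(self):
        jg, _ = self._setup({((100, 300), (400, 620)): 2})
        assert jg.edge_weight[((100, 300), (400, 620))] == 2

    def test_below_threshold_unchanged(self):
        jg, _ = self._setup({((100, 300), (400, 620)): 1})
        assert jg.edge_weight[((100, 300), (400, 620))] == 0

    def test_promotes_weight_one_edge(self):
        jg, _ = self._setup({((100, 300), (400, 500)): 5})
        assert jg.edge_weight[((100, 300), (400, 500))] == 2

    def test_zero_promotion_can_be_restricted(self):
        jg, _ = self._setup({((100, 300), (400, 620)): 4}, promote_zero=False)
        assert jg.edge_weight[((100, 300), (400, 620))] == 0

    def test_monotone_and_idempotent(self):
        jg, g = self._setup({((100, 300), (400, 500)): 5, ((220, 300), (400, 620)): 3})
        before = dict(jg.edge_weight)
        again = sc.promote_paired_edges(jg, g, min_pairs=2)
        assert again.edge_weight == before
        assert all(w in (0, 1, 2) for w in again.edge_weight.values())


def _check_assignment_constraints(jg, g):
    """Weight-1 edges across each interior exon restate the program's
    constraints: the larger side assigned exactly once, the smaller side
    covered at least once."""
    cov = jg.node_weight
    for v in g.nodes:
        ins = [k for k in cov if k[1] == v.start]
        outs = [k for k in cov if k[0] == v.end]
        if not ins or not outs:
            continue
        ones = {
            (i, o) for i in ins for o in outs if jg.edge_weight[(i, o)] == 1
        }
        if len(ins) >= len(outs):
            for i in ins:
                assert sum(1 for a, _ in ones if a == i) == 1
            for o in outs:
                assert sum(1 for _, b in ones if b == o) >= 1
        else:
            for o in outs:
                assert sum(1 for _, b in ones if b == o) == 1
            for i in ins:
                assert sum(1 for a, _ in ones if a == i) >= 1


def test_binpacking_weights_satisfy_constraints_on_random_graphs():
    rng = np.random.default_rng(17)
    for _ in range(60):
        g = sc.random_splicing_graph(rng)
        jg = sc.weight_edges_binpacking(sc.build_junction_graph(g), g)
        _check_assignment_constraints(jg, g)
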