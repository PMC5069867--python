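"""Weighted junction graphs.

The junction graph J of a splicing graph G is a line-graph construction:
each node of J is a junction edge of G (weighted by that junction's read
coverage) and J has a directed edge (i, j) exactly when i and j are incident
in G — the downstream exon of i is the upstream exon of j. Edge weights in J
take values {0, 1, 2}:

* 1 — the bin-packing assignment at the shared exon links the two junctions
  (their coverages balance, so they plausibly come from one transcript);
* 2 — at least ``min_pairs`` sequenced fragments span both junctions, the
  strongest evidence of co-occurrence;
* 0 — neither source of evidence supports the link; such an edge is never
  traversed by any predicted transcript.

At each exon with n in-junctions and m out-junctions (n >= m after role
normalization), the in-junctions are items sized by coverage and the
out-junctions bins with coverage capacities; the assignment minimizes the
sum of squared bin residuals subject to every item placed exactly once and
every bin receiving at least one item.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import AssemblyConfig, DEFAULT_CONFIG
from .splicing_graph import JunctionKey, SplicingGraph

JGEdge = tuple[JunctionKey, JunctionKey]


@dataclass
class JunctionGraph:
    """Line graph of a splicing graph, weighted on nodes and edges."""

    locus_id: str
    node_weight: dict[JunctionKey, int]
    edge_weight: dict[JGEdge, int]

    def out_neighbors(self, k: JunctionKey) -> list[JunctionKey]:
        return sorted(j for (i, j) in self.edge_weight if i == k)

    def in_neighbors(self, k: JunctionKey) -> list[JunctionKey]:
        return sorted(i for (i, j) in self.edge_weight if j == k)

    def to_json_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "nodes": [
                {"junction": list(k), "weight": w}
                for k, w in sorted(self.node_weight.items())
            ],
            "edges": [
                {"from": list(i), "to": list(j), "weight": w}
                for (i, j), w in sorted(self.edge_weight.items())
            ],
        }


@dataclass
class BinPackingInstance:
    """One exon's in/out junction assignment problem.

    ``items`` are the coverages of the larger-cardinality side, ``bins`` the
    coverages of the smaller side. After solving, ``assignment[j]`` is the
    bin index receiving item j and ``z`` the achieved objective
    sum_i (c_i - sum_{j in bin i} s_j)^2.
    """

    items: list[int]
    bins: list[int]
    assignment: Optional[list[int]] = None
    z: Optional[int] = None

    def objective(self, assignment: Sequence[int]) -> int:
        loads = [0] * len(self.bins)
        for j, i in enumerate(assignment):
            loads[i] += self.items[j]
        return sum((c - l) ** 2 for c, l in zip(self.bins, loads))


def _solve_exact(inst: BinPackingInstance) -> tuple[list[int], int]:
    """Branch-and-bound over surjective assignments.

    Items are assigned in the given order, bins explored in index order, and
    only strictly better objectives replace the incumbent — so among equal-z
    optima the lexicographically smallest assignment vector wins, which
    (with items and bins pre-sorted by coverage desc, coordinate asc) is the
    documented deterministic tie-break.
    """
    n, m = len(inst.items), len(inst.bins)
    sizes, caps = inst.items, inst.bins
    best_z = None
    best: list[int] = []
    assign = [0] * n
    loads = [0] * m

    def bound(j: int, empty: int) -> int:
        # bins can only gain load, so overfill penalties are irrevocable
        return sum((l - c) ** 2 for l, c in zip(loads, caps) if l > c)

    def rec(j: int, empty: int) -> None:
        nonlocal best_z, best
        if n - j < empty:
            return  # not enough items left to fill every empty bin
        if j == n:
            z = sum((c - l) ** 2 for c, l in zip(caps, loads))
            if best_z is None or z < best_z:
                best_z, best = z, assign.copy()
            return
        if best_z is not None and bound(j, empty) >= best_z:
            return
        for i in range(m):
            was_empty = loads[i] == 0
            loads[i] += sizes[j]
            assign[j] = i
            rec(j + 1, empty - was_empty)
            loads[i] -= sizes[j]
        assign[j] = 0

    rec(0, m)
    assert best_z is not None
    return best, best_z


def _greedy_start(
    sizes: Sequence[int], caps: Sequence[int], best_fit: bool
) -> list[int]:
    """Size-ordered greedy placement with a surjectivity guard.

    ``best_fit``: each item goes to the bin minimizing the objective
    increment; otherwise classic first fit (first bin with room, else the
    least-loaded bin). When only as many items remain as empty bins, empty
    bins are filled first so every bin receives an item.
    """
    n, m = len(sizes), len(caps)
    order = sorted(range(n), key=lambda j: (-sizes[j], j))
    assign = [0] * n
    loads = [0] * m
    for idx, j in enumerate(order):
        empty = [i for i in range(m) if loads[i] == 0]
        if 0 < len(empty) == n - idx:
            i = empty[0]
        elif best_fit:
            i = min(
                range(m),
                key=lambda i: (
                    (caps[i] - loads[i] - sizes[j]) ** 2 - (caps[i] - loads[i]) ** 2,
                    i,
                ),
            )
        else:
            fits = [i for i in range(m) if loads[i] + sizes[j] <= caps[i]]
            i = fits[0] if fits else min(range(m), key=lambda i: (loads[i], i))
        assign[j] = i
        loads[i] += sizes[j]
    return assign


def _solve_heuristic(inst: BinPackingInstance) -> tuple[list[int], int]:
    """Greedy start + first-improvement local search (moves, swaps).

    The start is the better of best-fit decreasing and size-ordered first
    fit, and local search never worsens, so the result is always at least
    as good as the first-fit baseline.
    """
    n, m = len(inst.items), len(inst.bins)
    sizes, caps = inst.items, inst.bins
    starts = [
        _greedy_start(sizes, caps, best_fit=True),
        _greedy_start(sizes, caps, best_fit=False),
    ]
    assign = min(starts, key=lambda a: inst.objective(a))
    loads = [0] * m
    for j, i in enumerate(assign):
        loads[i] += sizes[j]

    def z_of() -> int:
        return sum((c - l) ** 2 for c, l in zip(caps, loads))

    improved = True
    guard = 0
    while improved and guard < 10_000:
        improved = False
        guard += 1
        z = z_of()
        # single-item relocation
        for j in range(n):
            src = assign[j]
            if sum(1 for a in assign if a == src) == 1:
                continue
            for i in range(m):
                if i == src:
                    continue
                loads[src] -= sizes[j]
                loads[i] += sizes[j]
                if z_of() < z:
                    assign[j] = i
                    improved = True
                    break
                loads[src] += sizes[j]
                loads[i] -= sizes[j]
            if improved:
                break
        if improved:
            continue
        # pairwise swap
        for j1 in range(n):
            for j2 in range(j1 + 1, n):
                i1, i2 = assign[j1], assign[j2]
                if i1 == i2:
                    continue
                loads[i1] += sizes[j2] - sizes[j1]
                loads[i2] += sizes[j1] - sizes[j2]
                if z_of() < z:
                    assign[j1], assign[j2] = i2, i1
                    improved = True
                    break
                loads[i1] -= sizes[j2] - sizes[j1]
                loads[i2] -= sizes[j1] - sizes[j2]
            if improved:
                break
    return assign, z_of()


def solve_binpacking(
    inst: BinPackingInstance,
    mode: str = "auto",
    exact_assignment_limit: int = DEFAULT_CONFIG.exact_assignment_limit,
) -> BinPackingInstance:
    """Solve the quadratic assignment; requires len(items) >= len(bins) >= 1.

    ``mode`` is "exact" (global optimum via branch-and-bound), "heuristic"
    (local optimum), or "auto" (exact while the assignment space
    bins**items stays within ``exact_assignment_limit``).
    """
    n, m = len(inst.items), len(inst.bins)
    if m < 1 or n < m:
        raise ValueError(f"need n >= m >= 1, got n={n}, m={m}")
    if mode == "auto":
        mode = "exact" if m**n <= exact_assignment_limit else "heuristic"
    if mode == "exact":
        inst.assignment, inst.z = _solve_exact(inst)
    elif mode == "heuristic":
        inst.assignment, inst.z = _solve_heuristic(inst)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return inst


def build_junction_graph(g: SplicingGraph) -> JunctionGraph:
    """Line-graph construction; all edge weights start at 0."""
    node_weight = {e.key: e.coverage for e in g.edges}
    edge_weight: dict[JGEdge, int] = {}
    for v in g.nodes:
        ins = sorted(k for k in node_weight if k[1] == v.start)
        outs = sorted(k for k in node_weight if k[0] == v.end)
        for i in ins:
            for j in outs:
                edge_weight[(i, j)] = 0
    return JunctionGraph(g.locus_id, node_weight, edge_weight)


def weight_edges_binpacking(
    jg: JunctionGraph,
    g: SplicingGraph,
    mode: str = "auto",
    exact_assignment_limit: int = DEFAULT_CONFIG.exact_assignment_limit,
) -> JunctionGraph:
    """Assign weight 1 to the junction pairs selected by bin-packing.

    Each interior exon (>=1 in-junction and >=1 out-junction) is solved
    independently. When out-junctions outnumber in-junctions the roles are
    swapped (the model is symmetric under edge-direction reversal). Items
    and bins are ordered by (coverage desc, genomic coordinate asc) so the
    exact solver's lexicographic preference is a platform-independent
    tie-break.
    """
    cov = jg.node_weight
    for v in g.nodes:
        ins = [k for k in cov if k[1] == v.start]
        outs = [k for k in cov if k[0] == v.end]
        if not ins or not outs:
            continue
        ins.sort(key=lambda k: (-cov[k], k))
        outs.sort(key=lambda k: (-cov[k], k))
        swapped = len(outs) > len(ins)
        items, bins = (outs, ins) if swapped else (ins, outs)
        inst = BinPackingInstance([cov[k] for k in items], [cov[k] for k in bins])
        solve_binpacking(inst, mode, exact_assignment_limit)
        assert inst.assignment is not None
        for j, i in enumerate(inst.assignment):
            pair = (bins[i], items[j]) if swapped else (items[j], bins[i])
            jg.edge_weight[pair] = max(jg.edge_weight.get(pair, 0), 1)
    return jg


def promote_paired_edges(
    jg: JunctionGraph,
    g: SplicingGraph,
    min_pairs: int = DEFAULT_CONFIG.min_pairs,
    promote_zero_weight: bool = True,
) -> JunctionGraph:
    """Raise to 2 every edge whose junction pair has enough mate support.

    With ``promote_zero_weight`` (the default, the literal reading of the
    weighting rule) promotion applies regardless of the bin-packing weight,
    resurrecting weight-0 links; otherwise only weight-1 edges are promoted.
    Never decreases a weight; idempotent.
    """
    for pair, count in g.pair_support.items():
        if count < min_pairs:
            continue
        if pair not in jg.edge_weight:
            continue
        if jg.edge_weight[pair] >= 1 or promote_zero_weight:
            jg.edge_weight[pair] = 2
    return jg
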