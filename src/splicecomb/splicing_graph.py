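"""Per-locus splicing graphs.

A splicing graph is the per-gene-locus DAG whose nodes are exonic segments —
maximal genomic intervals of contiguous read coverage, split at every splice
donor/acceptor site — and whose directed edges are splice junctions, weighted
by the number of reads spanning them. A node is not necessarily a whole
biological exon: internal splice sites of other isoforms produce partial-exon
nodes.

Construction proceeds in four steps, mirroring how the evidence accumulates:

1. ``cluster_loci`` groups alignments into gene loci (connected components
   under block overlap, shared junctions, mate pairing, and near-adjacency of
   coverage islands).
2. ``build_graph`` derives the coverage profile, the junction set and the
   per-fragment junction chains for one locus.
3. ``repair_fragmented_exons`` bridges coverage gaps inside exons of lowly
   expressed genes using mate pairs.
4. ``split_pseudo_exons`` removes low-coverage runs caused by reads wrongly
   mapped into introns (pseudo exons) with a sliding-window statistic.

The graph is stored as a coverage vector plus a junction multiset; nodes and
edges are re-derived from these after every correction, which makes the
corrections naturally idempotent.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignments_io import Junction, SplicedAlignment, junctions_of
from .config import AssemblyConfig, DEFAULT_CONFIG, log

JunctionKey = tuple[int, int]  # (donor_end, acceptor_start)


@dataclass(frozen=True)
class Fragment:
    """Evidence of one sequenced fragment: per-read exonic blocks plus the
    set of junction keys spanned by either read."""

    reads: tuple[tuple[tuple[int, int], ...], ...]
    junction_keys: tuple[JunctionKey, ...]


@dataclass
class ExonNode:
    """An exonic segment with its per-base coverage."""

    interval: tuple[int, int]
    kind: str  # internal | terminal-left | terminal-right | single
    coverage: np.ndarray

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def mean_coverage(self) -> float:
        return float(self.coverage.mean()) if self.length else 0.0


@dataclass(frozen=True)
class Edge:
    """A splice junction edge between two nodes, weighted by read support."""

    donor_end: int
    acceptor_start: int
    coverage: int

    @property
    def key(self) -> JunctionKey:
        return (self.donor_end, self.acceptor_start)


class SplicingGraph:
    """Locus coverage + junctions, with nodes/edges derived on demand."""

    def __init__(
        self,
        locus_id: str,
        ref_name: str,
        strand: str,
        offset: int,
        cov: np.ndarray,
        junctions: dict[JunctionKey, int],
        fragments: Sequence[Fragment] = (),
        pair_support_override: Optional[dict[tuple[JunctionKey, JunctionKey], int]] = None,
    ) -> None:
        self.locus_id = locus_id
        self.ref_name = ref_name
        self.strand = strand
        self.offset = offset
        self.cov = np.asarray(cov, dtype=np.int64)
        self.junctions = dict(junctions)
        self.fragments = list(fragments)
        self._pair_support_override = pair_support_override
        self._derived: Optional[tuple[list[ExonNode], list[Edge]]] = None

    # ---------------------------------------------------------------- nodes

    def _islands(self) -> list[tuple[int, int]]:
        """Maximal runs of positive coverage, in genomic coordinates."""
        nz = self.cov > 0
        if not nz.any():
            return []
        d = np.diff(nz.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if nz[0]:
            starts.insert(0, 0)
        if nz[-1]:
            ends.append(len(nz))
        return [(s + self.offset, e + self.offset) for s, e in zip(starts, ends)]

    def _derive(self) -> tuple[list[ExonNode], list[Edge]]:
        donors = {d for d, _ in self.junctions}
        acceptors = {a for _, a in self.junctions}
        boundaries = sorted(donors | acceptors)
        nodes: list[ExonNode] = []
        for s, e in self._islands():
            cuts = [s] + [b for b in boundaries if s < b < e] + [e]
            for i in range(len(cuts) - 1):
                ns, ne = cuts[i], cuts[i + 1]
                left_splice = ns in acceptors or ns in donors
                right_splice = ne in donors or ne in acceptors
                if left_splice and right_splice:
                    kind = "internal"
                elif right_splice:
                    kind = "terminal-left"
                elif left_splice:
                    kind = "terminal-right"
                else:
                    kind = "single"
                nodes.append(
                    ExonNode(
                        (ns, ne),
                        kind,
                        self.cov[ns - self.offset : ne - self.offset],
                    )
                )
        by_end = {n.end: n for n in nodes}
        by_start = {n.start: n for n in nodes}
        edges = []
        for (d, a), cnt in sorted(self.junctions.items()):
            if d in by_end and a in by_start:
                edges.append(Edge(d, a, cnt))
            else:
                log.debug(
                    "%s: junction (%d,%d) lost its coverage flank", self.locus_id, d, a
                )
        return nodes, edges

    @property
    def nodes(self) -> list[ExonNode]:
        if self._derived is None:
            self._derived = self._derive()
        return self._derived[0]

    @property
    def edges(self) -> list[Edge]:
        if self._derived is None:
            self._derived = self._derive()
        return self._derived[1]

    def node_starting_at(self, pos: int) -> Optional[ExonNode]:
        for n in self.nodes:
            if n.start == pos:
                return n
        return None

    def node_ending_at(self, pos: int) -> Optional[ExonNode]:
        for n in self.nodes:
            if n.end == pos:
                return n
        return None

    def _invalidate(self) -> None:
        self._derived = None

    # --------------------------------------------------------- pair support

    @property
    def pair_support(self) -> dict[tuple[JunctionKey, JunctionKey], int]:
        """Fragments jointly supporting each incident edge pair.

        A fragment supports the incident pair (e1, e2) when the junctions of
        e1 and e2 are both spanned by its reads (one read may span both, which
        is strictly stronger evidence than a mate pair and counts equally).
        Keys are restricted to pairs incident in the current graph: the
        downstream node of e1 is the upstream node of e2.
        """
        if self._pair_support_override is not None:
            return self._pair_support_override
        edge_keys = {e.key for e in self.edges}
        starts = {n.start: n for n in self.nodes}
        counts: dict[tuple[JunctionKey, JunctionKey], int] = defaultdict(int)
        for frag in self.fragments:
            ks = [k for k in frag.junction_keys if k in edge_keys]
            for i, k1 in enumerate(ks):
                for k2 in ks[i + 1 :]:
                    if k1[1] > k2[0]:
                        continue
                    shared = starts.get(k1[1])
                    if shared is not None and shared.end == k2[0]:
                        counts[(k1, k2)] += 1
        return dict(counts)

    # ---------------------------------------------------------------- dumps

    def to_json_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "ref_name": self.ref_name,
            "strand": self.strand,
            "nodes": [
                {
                    "start": n.start,
                    "end": n.end,
                    "kind": n.kind,
                    "mean_coverage": round(n.mean_coverage, 3),
                }
                for n in self.nodes
            ],
            "edges": [
                {"donor_end": e.donor_end, "acceptor_start": e.acceptor_start, "coverage": e.coverage}
                for e in self.edges
            ],
            "pair_support": [
                {"e1": list(k1), "e2": list(k2), "count": c}
                for (k1, k2), c in sorted(self.pair_support.items())
            ],
        }

    def to_dot(self) -> str:
        lines = [f'digraph "{self.locus_id}" {{', "  rankdir=LR;"]
        for n in self.nodes:
            lines.append(
                f'  "{n.start}_{n.end}" [label="[{n.start},{n.end}) '
                f'{n.mean_coverage:.1f}x {n.kind}"];'
            )
        for e in self.edges:
            u = self.node_ending_at(e.donor_end)
            v = self.node_starting_at(e.acceptor_start)
            if u and v:
                lines.append(
                    f'  "{u.start}_{u.end}" -> "{v.start}_{v.end}" [label="{e.coverage}"];'
                )
        lines.append("}")
        return "\n".join(lines)


# ------------------------------------------------------------------ clustering


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass
class LocusReads:
    """A clustered gene locus: its alignments and strand call."""

    ref_name: str
    strand: str
    reads: list[SplicedAlignment]

    @property
    def start(self) -> int:
        return min(a.start for a in self.reads)

    @property
    def end(self) -> int:
        return max(a.end for a in self.reads)


def cluster_loci(
    alignments: Sequence[SplicedAlignment], max_gap: int = DEFAULT_CONFIG.max_gap
) -> list[LocusReads]:
    """Cluster one reference's alignments into gene loci.

    Two alignments share a locus iff they are transitively connected by
    exonic-block overlap, a shared junction, mate pairing, or coverage
    islands separated by less than ``max_gap`` bp. Loci with conflicting
    strand evidence are split by strand; untagged reads follow the locus
    strand when it is unambiguous, otherwise they are assigned to both
    strand loci.
    """
    if not alignments:
        return []
    ref = alignments[0].ref_name
    # merge all blocks (allowing max_gap) into super-islands
    blocks = sorted(b for a in alignments for b in a.blocks)
    islands: list[list[int]] = []
    for s, e in blocks:
        if islands and s <= islands[-1][1] + max_gap:
            islands[-1][1] = max(islands[-1][1], e)
        else:
            islands.append([s, e])
    starts = [i[0] for i in islands]
    uf = _UnionFind(len(islands))

    def island_of(pos: int) -> int:
        # rightmost island with start <= pos
        lo, hi = 0, len(starts) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if starts[mid] <= pos:
                lo = mid
            else:
                hi = mid - 1
        return lo

    by_qname: dict[str, list[int]] = defaultdict(list)
    read_islands: list[list[int]] = []
    for idx, a in enumerate(alignments):
        isl = sorted({island_of(b[0]) for b in a.blocks})
        read_islands.append(isl)
        for i in isl[1:]:
            uf.union(isl[0], i)
        if a.mate_id is not None:
            by_qname[a.read_id].append(idx)
    for idxs in by_qname.values():
        if len(idxs) > 1:
            a0 = read_islands[idxs[0]][0]
            for j in idxs[1:]:
                uf.union(a0, read_islands[j][0])

    comp_reads: dict[int, list[SplicedAlignment]] = defaultdict(list)
    for idx, a in enumerate(alignments):
        comp_reads[uf.find(read_islands[idx][0])].append(a)

    loci: list[LocusReads] = []
    for root in sorted(comp_reads, key=lambda r: islands[r][0]):
        reads = comp_reads[root]
        strands = Counter(a.strand_tag for a in reads if a.strand_tag in "+-")
        if len(strands) <= 1:
            strand = next(iter(strands), "?")
            loci.append(LocusReads(ref, strand, reads))
        else:
            untagged = [a for a in reads if a.strand_tag not in "+-"]
            for strand in ("+", "-"):
                sub = [a for a in reads if a.strand_tag == strand] + untagged
                sub.sort(key=lambda a: (a.start, a.read_id))
                loci.append(LocusReads(ref, strand, sub))
    return loci


# ----------------------------------------------------------------- building


def _group_fragments(reads: Sequence[SplicedAlignment]) -> list[Fragment]:
    by_id: dict[str, list[SplicedAlignment]] = defaultdict(list)
    singles: list[Fragment] = []
    for a in reads:
        if a.mate_id is not None:
            by_id[a.read_id].append(a)
        else:
            singles.append(
                Fragment(
                    (tuple(a.blocks),),
                    tuple(sorted(j.key for j in junctions_of(a))),
                )
            )
    frags = singles
    for rid in sorted(by_id):
        group = by_id[rid]
        keys = sorted({j.key for a in group for j in junctions_of(a)})
        frags.append(Fragment(tuple(tuple(a.blocks) for a in group), tuple(keys)))
    return frags


def build_graph(
    locus: LocusReads,
    locus_id: str = "locus",
    config: AssemblyConfig = DEFAULT_CONFIG,
) -> SplicingGraph:
    """Build the splicing graph for one clustered locus.

    Junctions supported by at least ``config.min_junction_reads`` spliced
    reads become edges with that read count as coverage. Per-fragment
    junction chains are retained for mate-pair weighting downstream.
    """
    reads = locus.reads
    if not reads:
        raise ValueError("empty locus")
    offset = min(a.start for a in reads)
    end = max(a.end for a in reads)
    cov = np.zeros(end - offset, dtype=np.int64)
    jc: Counter[JunctionKey] = Counter()
    for a in reads:
        for s, e in a.blocks:
            cov[s - offset : e - offset] += 1
        for j in junctions_of(a):
            jc[j.key] += 1
    junctions = {
        k: c for k, c in jc.items() if c >= config.min_junction_reads
    }
    return SplicingGraph(
        locus_id=locus_id,
        ref_name=locus.ref_name,
        strand=locus.strand,
        offset=offset,
        cov=cov,
        junctions=junctions,
        fragments=_group_fragments(reads),
    )


# ------------------------------------------------------------------- repair


def _overlaps(blocks: Iterable[tuple[int, int]], s: int, e: int) -> bool:
    return any(bs < e and be > s for bs, be in blocks)


def repair_fragmented_exons(
    g: SplicingGraph,
    max_fill: int = DEFAULT_CONFIG.max_fill,
    min_pairs: int = DEFAULT_CONFIG.min_pairs,
) -> SplicingGraph:
    """Merge coverage islands broken by low expression.

    Two neighbouring islands with no junction between them are merged when at
    least ``min_pairs`` fragments place one read on each island and the gap
    is at most ``max_fill`` bp; the gap is filled with the rounded mean of
    the two islands' coverages. Applied to a fixpoint, so chains of islands
    merge transitively; never crosses a splice boundary (a gap flanked or
    spanned by a recorded junction is a real intron).
    """
    g = SplicingGraph(
        g.locus_id, g.ref_name, g.strand, g.offset, g.cov.copy(),
        g.junctions, g.fragments, g._pair_support_override,
    )
    paired = [f for f in g.fragments if len(f.reads) > 1]
    changed = True
    while changed:
        changed = False
        islands = g._islands()
        for (xs, xe), (ys, ye) in zip(islands, islands[1:]):
            if ys - xe > max_fill:
                continue
            if any(
                d == xe or a == ys or (d <= xe and a >= ys)
                for d, a in g.junctions
            ):
                continue
            n = sum(
                1
                for f in paired
                if any(_overlaps(r, xs, xe) for r in f.reads)
                and any(_overlaps(r, ys, ye) for r in f.reads)
            )
            if n < min_pairs:
                continue
            o = g.offset
            fill = max(
                1,
                round(
                    (g.cov[xs - o : xe - o].mean() + g.cov[ys - o : ye - o].mean()) / 2
                ),
            )
            g.cov[xe - o : ys - o] = fill
            changed = True
            break
    g._invalidate()
    return g


# ------------------------------------------------------- pseudo-exon removal


def _smooth(c: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of width ~w with edge clipping."""
    half = w // 2
    cs = np.concatenate([[0], np.cumsum(c)])
    idx = np.arange(len(c))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(c))
    return (cs[hi] - cs[lo]) / (hi - lo)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _node_low_runs(
    c: np.ndarray, w: int, drop_ratio: float
) -> list[tuple[int, int]]:
    """Confirmed low-coverage runs inside one node's coverage vector.

    Candidates are found on the w-smoothed profile (below drop_ratio x the
    profile maximum), their boundaries refined to the per-base step using the
    midpoint between run and flank coverage, and each run is confirmed
    against the sliding-window rule: mean coverage below drop_ratio x the
    minimum of the flanking window means.
    """
    L = len(c)
    if L <= 2 * w:
        return []
    s = _smooth(c, w)
    thr0 = drop_ratio * s.max()
    out = []
    for a0, b0 in _runs(s < thr0):
        run_mean = c[a0:b0].mean()
        flanks0 = []
        if a0 > 0:
            flanks0.append(c[max(0, a0 - w) : a0].mean())
        if b0 < L:
            flanks0.append(c[b0 : min(L, b0 + w)].mean())
        if not flanks0:
            continue
        thr_b = (run_mean + min(flanks0)) / 2
        a, b = a0, b0
        while a > 0 and c[a - 1] < thr_b:
            a -= 1
        while a < b and c[a] >= thr_b:
            a += 1
        while b < L and c[b] < thr_b:
            b += 1
        while b > a and c[b - 1] >= thr_b:
            b -= 1
        if b - a < w:
            continue
        flanks = []
        if a > 0:
            flanks.append(c[max(0, a - w) : a].mean())
        if b < L:
            flanks.append(c[b : min(L, b + w)].mean())
        if c[a:b].mean() < drop_ratio * min(flanks):
            out.append((a, b))
    return out


def split_pseudo_exons(
    g: SplicingGraph,
    window: int = DEFAULT_CONFIG.window,
    drop_ratio: float = DEFAULT_CONFIG.drop_ratio,
) -> SplicingGraph:
    """Correct wrongly merged (pseudo) exons with a sliding window.

    Two complementary applications of the same flank-relative statistic:

    * within a node longer than 2 x window, a confirmed low-coverage run is
      excised — splitting the node in two (interior run) or trimming it
      (terminal run at a splice-free end);
    * a node with no incident splice edge, inside a locus that has splice
      edges, is discarded entirely when its mean coverage is below
      drop_ratio x the mean coverage of the nearest splice-attached nodes —
      the pseudo-exon case proper, where reads wrongly mapped into an intron
      form a coverage segment between two real exons.

    Splice-attached node ends are never trimmed, so every junction keeps its
    coverage flanks. Idempotent: re-deriving nodes from the cleaned coverage
    leaves nothing further to remove.
    """
    donors = {d for d, _ in g.junctions}
    acceptors = {a for _, a in g.junctions}
    o = g.offset
    cov = g.cov.copy()

    for node in g.nodes:
        c = node.coverage
        for a, b in _node_low_runs(np.asarray(c, dtype=float), window, drop_ratio):
            if a == 0 and node.start in acceptors:
                continue  # left end anchors an in-junction
            if b == node.length and node.end in donors:
                continue  # right end anchors an out-junction
            cov[node.start + a - o : node.start + b - o] = 0

    has_edges = len(g.edges) > 0
    if has_edges:
        # a node is splice-attached iff some edge starts or ends on it
        attached = [
            n for n in g.nodes if n.start in acceptors or n.end in donors
        ]
        for node in g.nodes:
            if node in attached:
                continue
            left = [n for n in attached if n.end <= node.start]
            right = [n for n in attached if n.start >= node.end]
            refs = []
            if left:
                refs.append(left[-1].mean_coverage)
            if right:
                refs.append(right[0].mean_coverage)
            if refs and node.mean_coverage < drop_ratio * min(refs):
                cov[node.start - o : node.end - o] = 0

    return SplicingGraph(
        g.locus_id, g.ref_name, g.strand, g.offset, cov,
        g.junctions, g.fragments, g._pair_support_override,
    )
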