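"""Transcript recovery from weighted junction graphs, and the pipeline driver.

Path extraction is seed-and-extend on the junction graph: the highest-weight
junction not yet covered by any predicted path seeds a new path, which is
extended rightward and then leftward, at each step taking an edge of maximal
priority (weight 2 beats 1; weight-0 edges are untraversable) until no
traversable edge remains. The loop repeats until every junction lies in at
least one path, so no observed junction is left unexplained. Paths may share
junctions; identical intron chains collapse to one transcript.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

from .alignments_io import read_alignments
from .config import AssemblyConfig, DEFAULT_CONFIG, log
from .junction_graph import (
    JunctionGraph,
    build_junction_graph,
    promote_paired_edges,
    weight_edges_binpacking,
)
from .splicing_graph import (
    JunctionKey,
    LocusReads,
    SplicingGraph,
    build_graph,
    cluster_loci,
    repair_fragmented_exons,
    split_pseudo_exons,
)


@dataclass
class TranscriptPath:
    """An ordered chain of junction-graph nodes predicted to co-occur."""

    locus_id: str
    nodes: list[JunctionKey]
    seed_index: int
    edge_weights: list[int]

    @property
    def seed(self) -> JunctionKey:
        return self.nodes[self.seed_index]


@dataclass
class Transcript:
    """A recovered transcript: an exon chain with expression and provenance."""

    transcript_id: str
    locus_id: str
    ref_name: str
    strand: str
    exons: list[tuple[int, int]]
    seed: Optional[JunctionKey] = None  # None marks a single-exon transcript
    seed_coverage: int = 0
    mean_depth: float = 0.0
    expression: float = 0.0
    source_path: Optional[TranscriptPath] = None

    @property
    def intron_chain(self) -> tuple[JunctionKey, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def extract_paths(jg: JunctionGraph) -> list[TranscriptPath]:
    """Seed-and-extend path extraction.

    Seeds are drawn from junctions not yet in any path, highest node weight
    first (ties: smaller genomic coordinate). Extension prefers weight-2
    over weight-1 edges and never takes weight-0; ties are broken toward the
    higher-weight neighbor, then the smaller coordinate.
    """
    nodes = sorted(jg.node_weight)
    if not nodes:
        return []
    out_adj: dict[JunctionKey, list[JunctionKey]] = defaultdict(list)
    in_adj: dict[JunctionKey, list[JunctionKey]] = defaultdict(list)
    for (i, j), w in jg.edge_weight.items():
        out_adj[i].append(j)
        in_adj[j].append(i)

    def step(cur: JunctionKey, adj, key) -> Optional[JunctionKey]:
        cands = [
            (n, jg.edge_weight[key(cur, n)])
            for n in adj[cur]
            if jg.edge_weight[key(cur, n)] >= 1
        ]
        if not cands:
            return None
        return min(cands, key=lambda t: (-t[1], -jg.node_weight[t[0]], t[0]))[0]

    covered: set[JunctionKey] = set()
    paths: list[TranscriptPath] = []
    while len(covered) < len(nodes):
        seed = min(
            (k for k in nodes if k not in covered),
            key=lambda k: (-jg.node_weight[k], k),
        )
        right: list[JunctionKey] = []
        cur = seed
        while True:
            nxt = step(cur, out_adj, lambda c, n: (c, n))
            if nxt is None:
                break
            right.append(nxt)
            cur = nxt
        left: list[JunctionKey] = []
        cur = seed
        while True:
            prv = step(cur, in_adj, lambda c, n: (n, c))
            if prv is None:
                break
            left.append(prv)
            cur = prv
        chain = left[::-1] + [seed] + right
        weights = [
            jg.edge_weight[(chain[i], chain[i + 1])] for i in range(len(chain) - 1)
        ]
        paths.append(TranscriptPath(jg.locus_id, chain, len(left), weights))
        covered.update(chain)
    return paths


def _terminal_extent(g: SplicingGraph, pos: int, direction: int) -> int:
    """Extend a terminal exon through genomically contiguous nodes.

    ``direction`` -1 walks left from the node ending at ``pos``; +1 walks
    right from the node starting at ``pos``. Returns the coverage-supported
    outer coordinate.
    """
    if direction < 0:
        node = g.node_ending_at(pos)
        while node is not None:
            prev = g.node_ending_at(node.start)
            if prev is None:
                return node.start
            node = prev
        return pos
    node = g.node_starting_at(pos)
    while node is not None:
        nxt = g.node_starting_at(node.end)
        if nxt is None:
            return node.end
        node = nxt
    return pos


def paths_to_transcripts(
    paths: Sequence[TranscriptPath], g: SplicingGraph
) -> list[Transcript]:
    """Convert junction chains to exon chains; duplicates collapse.

    Internal exons are forced by the junctions; terminal exons extend to the
    coverage-supported ends of their (possibly partial-exon) nodes.
    """
    seen: dict[tuple[JunctionKey, ...], Transcript] = {}
    for p in paths:
        chain = p.nodes
        start = _terminal_extent(g, chain[0][0], -1)
        end = _terminal_extent(g, chain[-1][1], +1)
        exons = [(start, chain[0][0])]
        for i in range(len(chain) - 1):
            exons.append((chain[i][1], chain[i + 1][0]))
        exons.append((chain[-1][1], end))
        key = tuple(chain)
        seed_cov = g.junctions.get(p.seed, 0)
        if key in seen:
            if seed_cov > seen[key].seed_coverage:
                seen[key].seed_coverage = seed_cov
                seen[key].seed = p.seed
                seen[key].source_path = p
            continue
        seen[key] = Transcript(
            transcript_id="",
            locus_id=g.locus_id,
            ref_name=g.ref_name,
            strand=g.strand,
            exons=exons,
            seed=p.seed,
            seed_coverage=seed_cov,
            source_path=p,
        )
    return list(seen.values())


def filter_transcripts(
    transcripts: Sequence[Transcript],
    min_frac: float = 0.0,
    min_abs_cov: float = 0.0,
) -> list[Transcript]:
    """Locus-relative expression filter (plus optional absolute floor).

    A transcript is dropped when its expression is below ``min_frac`` times
    the maximum expression in its locus; ``min_frac = 0`` (the default)
    keeps every candidate.
    """
    if min_frac <= 0 and min_abs_cov <= 0:
        return list(transcripts)
    by_locus: dict[str, float] = defaultdict(float)
    for t in transcripts:
        by_locus[t.locus_id] = max(by_locus[t.locus_id], t.expression)
    return [
        t
        for t in transcripts
        if t.expression >= min_frac * by_locus[t.locus_id]
        and (min_abs_cov <= 0 or t.seed_coverage >= min_abs_cov or t.seed is None)
    ]


# ------------------------------------------------------------------ pipeline


@dataclass
class LocusResult:
    """Everything the pipeline derived for one locus (for inspection)."""

    locus_id: str
    graph_raw: SplicingGraph
    graph: SplicingGraph
    junction_graph: Optional[JunctionGraph]
    paths: list[TranscriptPath]
    transcripts: list[Transcript]


@dataclass
class AssemblyResult:
    transcripts: list[Transcript]
    loci: list[LocusResult]
    total_mapped_reads: int


def assemble_locus(
    locus: LocusReads,
    locus_id: str,
    config: AssemblyConfig = DEFAULT_CONFIG,
) -> LocusResult:
    """Run the full per-locus chain: graph, corrections, weighting, paths."""
    raw = build_graph(locus, locus_id, config)
    g = repair_fragmented_exons(raw, config.max_fill, config.min_pairs)
    g = split_pseudo_exons(g, config.window, config.drop_ratio)
    if not g.edges:
        transcripts = []
        for i, n in enumerate(g.nodes):
            if (
                n.length >= config.min_single_exon_len
                and n.mean_coverage >= config.min_single_exon_depth
            ):
                transcripts.append(
                    Transcript(
                        transcript_id="",
                        locus_id=locus_id,
                        ref_name=g.ref_name,
                        strand=g.strand,
                        exons=[n.interval],
                        seed=None,
                        mean_depth=n.mean_coverage,
                    )
                )
        return LocusResult(locus_id, raw, g, None, [], transcripts)
    jg = build_junction_graph(g)
    jg = weight_edges_binpacking(
        jg, g, mode="auto", exact_assignment_limit=config.exact_assignment_limit
    )
    jg = promote_paired_edges(jg, g, config.min_pairs, config.promote_zero_weight)
    paths = extract_paths(jg)
    transcripts = paths_to_transcripts(paths, g)
    return LocusResult(locus_id, raw, g, jg, paths, transcripts)


def assemble(
    source: Union[str, Iterable[tuple[str, list]]],
    config: AssemblyConfig = DEFAULT_CONFIG,
) -> AssemblyResult:
    """Assemble transcripts from a SAM/BAM path (or pre-grouped alignments).

    Returns the transcript set with expression estimates populated and the
    locus-relative filter applied (a no-op at the default ``min_frac = 0``).
    """
    from .expression import estimate  # local import to avoid a cycle

    if isinstance(source, str):
        groups = read_alignments(source, min_mapq=config.min_mapq)
    else:
        groups = source
    loci_results: list[LocusResult] = []
    total_reads = 0
    locus_no = 0
    for ref, reads in groups:
        total_reads += len(reads)
        for locus in cluster_loci(reads, config.max_gap):
            locus_no += 1
            loci_results.append(
                assemble_locus(locus, f"SC.{locus_no}", config)
            )
    transcripts: list[Transcript] = []
    for lr in loci_results:
        lr.transcripts.sort(key=lambda t: (t.start, t.intron_chain))
        for i, t in enumerate(lr.transcripts, 1):
            t.transcript_id = f"{lr.locus_id}.{i}"
            est = estimate(t, max(total_reads, 1), config.read_length)
            t.expression = est.fpkm
        transcripts.extend(lr.transcripts)
    transcripts = filter_transcripts(transcripts, config.min_frac, config.min_abs_cov)
    return AssemblyResult(transcripts, loci_results, total_reads)


def write_gtf(transcripts: Sequence[Transcript], out: TextIO) -> None:
    """Write transcripts as GTF2.2 (1-based inclusive coordinates)."""
    out.write("##format: gtf\n")
    ordered = sorted(transcripts, key=lambda t: (t.ref_name, t.start, t.transcript_id))
    for t in ordered:
        strand = t.strand if t.strand in "+-" else "."
        attrs = (
            f'gene_id "{t.locus_id}"; transcript_id "{t.transcript_id}"; '
            f'cov "{t.seed_coverage if t.seed else round(t.mean_depth, 3)}"; '
            f'FPKM "{t.expression:.4f}";'
        )
        out.write(
            f"{t.ref_name}\tsplicecomb\ttranscript\t{t.start + 1}\t{t.end}\t"
            f".\t{strand}\t.\t{attrs}\n"
        )
        for i, (s, e) in enumerate(t.exons, 1):
            out.write(
                f"{t.ref_name}\tsplicecomb\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f'{attrs} exon_number "{i}";\n'
            )
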