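"""Synthetic RNA-seq loci: spliced paired-end SAM plus ground truth.

The generator emulates the data regime the assembler targets —
strand-specific paired-end short reads over multi-isoform gene loci — at
desk scale: multi-isoform loci sharing exons, junction-spanning reads,
fragments drawn from a stated length distribution, coverage proportional to
per-isoform molar abundance, coverage gaps in lowly expressed exons, and
spurious intronic read noise. Reference bases are never needed (the
assembler consumes coordinates, not sequence), so SAM records carry real
coordinates on synthetic contigs with constant sequence/quality fields.

It does not model sequencing errors, positional/GC bias, or multi-mapping
ambiguity; conclusions from these fixtures speak to the combinatorial core
of the assembler, not to aligner artifacts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .splicing_graph import SplicingGraph


@dataclass
class SimLocus:
    """One synthetic gene locus.

    ``exons`` are template genomic intervals (0-based half-open, sorted,
    disjoint); each isoform is a strictly increasing list of exon indices.
    ``abundances`` are molar: expected fragment counts are proportional to
    abundance x transcript length. ``noise_rate`` is expected spurious reads
    per kb of intronic (non-exonic) locus sequence. ``bridge_pairs`` > 0
    guarantees that many mate pairs bridging every pair of consecutive
    junctions of each isoform (reads centered on the two junctions),
    emulating a library whose fragment distribution reliably spans shared
    exons.
    """

    ref_name: str
    ref_length: int
    exons: list[tuple[int, int]]
    isoforms: list[list[int]]
    abundances: list[float]
    n_fragments: int
    frag_mean: float = 300.0
    frag_sd: float = 25.0
    read_length: int = 100
    noise_rate: float = 0.0
    bridge_pairs: int = 0
    strand: str = "+"
    gene_id: str = "gene"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for iso in self.isoforms:
            if list(iso) != sorted(set(iso)):
                raise ValueError("isoform exon chain must be strictly increasing")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be positive")
        if len(self.abundances) != len(self.isoforms):
            raise ValueError("one abundance per isoform")

    def transcript_exons(self, iso: int) -> list[tuple[int, int]]:
        return [self.exons[i] for i in self.isoforms[iso]]

    def transcript_length(self, iso: int) -> int:
        return sum(e - s for s, e in self.transcript_exons(iso))


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    transcripts: list[dict]  # gene_id, transcript_id, ref, strand, exons
    abundances: dict[str, float]
    noise_segments: list[tuple[str, int, int]]  # noise-covered intronic runs


def _genomic_blocks(
    exons: Sequence[tuple[int, int]], t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic exonic blocks."""
    blocks = []
    pos = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(t_start - pos, 0), min(t_end - pos, length)
        if lo < hi:
            blocks.append((s + lo, s + hi))
        pos += length
    return blocks


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _sam_record(
    qname: str,
    flag: int,
    ref: str,
    blocks: Sequence[tuple[int, int]],
    mate_pos: int,
    tlen: int,
    read_length: int,
    xs: Optional[str],
) -> tuple[int, str]:
    pos = blocks[0][0]
    fields = [
        qname,
        str(flag),
        ref,
        str(pos + 1),
        "60",
        _cigar(blocks),
        "=" if flag & 1 else "*",
        str(mate_pos + 1) if flag & 1 else "0",
        str(tlen),
        "*",
        "*",
    ]
    if xs is not None and len(blocks) > 1:
        fields.append(f"XS:A:{xs}")
    return pos, "\t".join(fields)


def simulate(
    locus: SimLocus, rng: Optional[np.random.Generator] = None
) -> tuple[list[tuple[int, str]], SimTruth]:
    """Generate (position, SAM line) records and ground truth for one locus.

    Fragment counts per isoform are multinomial with probabilities
    proportional to abundance x transcript length; fragment lengths are
    normal (resampled, with a capped attempt count, when longer than the
    transcript); read starts are uniform within the transcript. Reads
    crossing an intron get an N CIGAR operation and an XS strand tag.
    Identical seeds give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(locus.seed)
    rl = locus.read_length
    k = len(locus.isoforms)
    weights = np.array(
        [locus.abundances[i] * locus.transcript_length(i) for i in range(k)], float
    )
    counts = rng.multinomial(locus.n_fragments, weights / weights.sum())
    records: list[tuple[int, str]] = []
    for iso in range(k):
        exons = locus.transcript_exons(iso)
        tlen_iso = locus.transcript_length(iso)
        for f in range(counts[iso]):
            frag = 0
            for _ in range(20):
                frag = int(round(rng.normal(locus.frag_mean, locus.frag_sd)))
                if rl <= frag <= tlen_iso:
                    break
            frag = min(max(frag, rl), tlen_iso)
            start = int(rng.integers(0, tlen_iso - frag + 1))
            qname = f"{locus.gene_id}_i{iso}_f{f}"
            b1 = _genomic_blocks(exons, start, start + rl)
            b2 = _genomic_blocks(exons, start + frag - rl, start + frag)
            tl = b2[-1][1] - b1[0][0]
            records.append(
                _sam_record(qname, 99, locus.ref_name, b1, b2[0][0], tl, rl, locus.strand)
            )
            records.append(
                _sam_record(qname, 147, locus.ref_name, b2, b1[0][0], -tl, rl, locus.strand)
            )
        # guaranteed junction-bridging mate pairs: for every pair of
        # consecutive junctions, fragments whose reads are centered on the
        # two junctions, so shared exons are always mate-bridged
        if locus.bridge_pairs > 0:
            junc_pos = []  # transcript coordinate of each junction
            acc = 0
            for s, e in exons[:-1]:
                acc += e - s
                junc_pos.append(acc)
            for jk in range(len(junc_pos) - 1):
                u1, u2 = junc_pos[jk], junc_pos[jk + 1]
                for b in range(locus.bridge_pairs):
                    t = max(u1 - rl // 2 - b, 0)
                    frag_end = min(u2 + rl // 2 + b, tlen_iso)
                    qname = f"{locus.gene_id}_i{iso}_bridge{jk}_{b}"
                    b1 = _genomic_blocks(exons, t, t + rl)
                    b2 = _genomic_blocks(exons, frag_end - rl, frag_end)
                    tl = b2[-1][1] - b1[0][0]
                    records.append(
                        _sam_record(qname, 99, locus.ref_name, b1, b2[0][0], tl, rl, locus.strand)
                    )
                    records.append(
                        _sam_record(qname, 147, locus.ref_name, b2, b1[0][0], -tl, rl, locus.strand)
                    )
    # spurious intronic noise: uniform single reads inside non-exonic gaps
    noise_cov: list[tuple[int, int]] = []
    if locus.noise_rate > 0:
        span_s = min(s for s, _ in locus.exons)
        span_e = max(e for _, e in locus.exons)
        exonic = sorted(locus.exons)
        gaps = []
        cur = span_s
        for s, e in exonic:
            if s > cur:
                gaps.append((cur, s))
            cur = max(cur, e)
        for i, (gs, ge) in enumerate(gaps):
            if ge - gs < rl:
                continue
            n = rng.poisson(locus.noise_rate * (ge - gs) / 1000.0)
            for j in range(int(n)):
                pos = int(rng.integers(gs, ge - rl + 1))
                records.append(
                    _sam_record(
                        f"{locus.gene_id}_noise{i}_{j}", 0, locus.ref_name,
                        [(pos, pos + rl)], 0, 0, rl, None,
                    )
                )
                noise_cov.append((pos, pos + rl))
    # merge noise read intervals into maximal covered runs
    noise_segments: list[tuple[str, int, int]] = []
    for s, e in sorted(noise_cov):
        if noise_segments and s <= noise_segments[-1][2]:
            last = noise_segments[-1]
            noise_segments[-1] = (last[0], last[1], max(last[2], e))
        else:
            noise_segments.append((locus.ref_name, s, e))
    truth_transcripts = [
        {
            "gene_id": locus.gene_id,
            "transcript_id": f"{locus.gene_id}.t{i + 1}",
            "ref_name": locus.ref_name,
            "strand": locus.strand,
            "exons": locus.transcript_exons(i),
        }
        for i in range(k)
    ]
    abund = {
        f"{locus.gene_id}.t{i + 1}": float(locus.abundances[i]) for i in range(k)
    }
    return records, SimTruth(truth_transcripts, abund, noise_segments)


def write_truth_gtf(transcripts: Sequence[dict], path: str) -> None:
    with open(path, "w") as out:
        out.write("##format: gtf\n")
        for t in transcripts:
            attrs = f'gene_id "{t["gene_id"]}"; transcript_id "{t["transcript_id"]}";'
            exons = t["exons"]
            out.write(
                f'{t["ref_name"]}\tsim\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}\t'
                f'.\t{t["strand"]}\t.\t{attrs}\n'
            )
            for i, (s, e) in enumerate(exons, 1):
                out.write(
                    f'{t["ref_name"]}\tsim\texon\t{s + 1}\t{e}\t.\t{t["strand"]}\t.\t'
                    f'{attrs} exon_number "{i}";\n'
                )


def simulate_dataset(
    loci: Sequence[SimLocus],
    out_dir: str,
    seed: int = 0,
    prefix: str = "sim",
) -> tuple[str, str, SimTruth]:
    """Simulate several loci into one coordinate-sorted SAM + truth GTF.

    Returns (sam_path, gtf_path, merged truth). One RNG seeded by ``seed``
    drives all loci, so the whole dataset is reproducible byte for byte.
    """
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    all_records: dict[str, list[tuple[int, str]]] = {}
    ref_lengths: dict[str, int] = {}
    transcripts: list[dict] = []
    abundances: dict[str, float] = {}
    noise_segments: list[tuple[str, int, int]] = []
    for locus in loci:
        recs, truth = simulate(locus, rng)
        all_records.setdefault(locus.ref_name, []).extend(recs)
        ref_lengths[locus.ref_name] = max(
            ref_lengths.get(locus.ref_name, 0), locus.ref_length
        )
        transcripts.extend(truth.transcripts)
        abundances.update(truth.abundances)
        noise_segments.extend(truth.noise_segments)
    sam_path = os.path.join(out_dir, f"{prefix}.sam")
    with open(sam_path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for ref in sorted(ref_lengths):
            out.write(f"@SQ\tSN:{ref}\tLN:{ref_lengths[ref]}\n")
        for ref in sorted(all_records):
            for _, line in sorted(all_records[ref], key=lambda r: (r[0], r[1])):
                out.write(line + "\n")
    gtf_path = os.path.join(out_dir, f"{prefix}_truth.gtf")
    write_truth_gtf(transcripts, gtf_path)
    with open(os.path.join(out_dir, f"{prefix}_truth.tsv"), "w") as out:
        out.write("transcript_id\tabundance\n")
        for tid in sorted(abundances):
            out.write(f"{tid}\t{abundances[tid]}\n")
    return sam_path, gtf_path, SimTruth(transcripts, abundances, noise_segments)


# ------------------------------------------------------------- study suites


def recovery_suite(
    seed: int,
    n_loci: int = 50,
    depth: float = 100.0,
    low_abundance: Optional[float] = None,
    noise_rate: float = 0.0,
    read_length: int = 100,
    spacing: int = 5000,
) -> list[SimLocus]:
    """Seeded loci for recovery studies: 1-3 isoforms, distinct abundances.

    Structures are built from proven alternative-splicing motifs (full
    chains plus exon skipping), with internal exons short enough that
    fragments regularly bridge both junctions of every shared exon. ``depth``
    is the target coverage of the most abundant isoform; ``low_abundance``,
    when given, adds one extra lowly expressed skipping isoform at that
    depth; ``noise_rate`` adds intronic noise (reads per intron kb).
    """
    rng = np.random.default_rng(seed)
    loci = []
    pos = 1000
    for li in range(n_loci):
        n_exons = int(rng.integers(3, 7))
        exons = []
        cur = pos
        for e in range(n_exons):
            if e == 0 or e == n_exons - 1:
                length = int(rng.integers(150, 300))
            else:
                length = int(rng.integers(80, 150))
            exons.append((cur, cur + length))
            cur += length + int(rng.integers(120, 500))
        full = list(range(n_exons))
        n_iso = int(rng.integers(1, 4))
        isoforms = [full]
        skippable = list(range(1, n_exons - 1))
        rng.shuffle(skippable)
        for k in range(n_iso - 1):
            if k < len(skippable):
                isoforms.append([i for i in full if i != skippable[k]])
        levels = [depth, depth * 0.3, depth * 0.1][: len(isoforms)]
        if low_abundance is not None and len(skippable) > len(isoforms) - 1:
            isoforms.append(
                [i for i in full if i != skippable[len(isoforms) - 1]]
            )
            levels.append(low_abundance)
        n_frag = int(
            round(
                sum(
                    lv * sum(e - s for s, e in (exons[i] for i in iso))
                    for lv, iso in zip(levels, isoforms)
                )
                / (2 * read_length)
            )
        )
        loci.append(
            SimLocus(
                ref_name="simchr",
                ref_length=cur + spacing * (n_loci + 1),
                exons=exons,
                isoforms=isoforms,
                abundances=levels,
                n_fragments=max(n_frag, 1),
                read_length=read_length,
                noise_rate=noise_rate,
                bridge_pairs=3,
                strand="+" if rng.integers(2) else "-",
                gene_id=f"g{li + 1}",
            )
        )
        pos = cur + spacing
    return loci


def random_splicing_graph(
    rng: np.random.Generator,
    max_exons: int = 8,
    max_cov: int = 50,
    locus_id: str = "rand",
) -> SplicingGraph:
    """A random valid splicing graph for constraint/property studies.

    Exonic segments on a line with random junctions between them (always
    left to right, so the DAG invariant holds), random edge coverages, and
    random mate-pair support on incident pairs.
    """
    n = int(rng.integers(3, max_exons + 1))
    exons = []
    cur = 100
    for _ in range(n):
        length = int(rng.integers(50, 200))
        exons.append((cur, cur + length))
        cur += length + int(rng.integers(60, 200))
    junctions: dict[tuple[int, int], int] = {}
    for i in range(n - 1):
        # always connect consecutive exons; extra skips at random
        junctions[(exons[i][1], exons[i + 1][0])] = int(rng.integers(1, max_cov + 1))
    for i in range(n - 2):
        for j in range(i + 2, n):
            if rng.random() < 0.25:
                junctions[(exons[i][1], exons[j][0])] = int(
                    rng.integers(1, max_cov + 1)
                )
    offset = exons[0][0]
    cov = np.zeros(exons[-1][1] - offset, dtype=np.int64)
    for s, e in exons:
        cov[s - offset : e - offset] = int(rng.integers(5, 80))
    pair_support: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    keys = sorted(junctions)
    for k1 in keys:
        for k2 in keys:
            if k1[1] <= k2[0] and any(s == k1[1] and e == k2[0] for s, e in exons):
                if rng.random() < 0.4:
                    pair_support[(k1, k2)] = int(rng.integers(0, 5))
    return SplicingGraph(
        locus_id=locus_id,
        ref_name="randchr",
        strand="+",
        offset=offset,
        cov=cov,
        junctions=junctions,
        fragments=(),
        pair_support_override=pair_support,
    )
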