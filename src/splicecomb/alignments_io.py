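"""Reading spliced alignments from SAM/BAM.

Each primary alignment is reduced to its exonic blocks: maximal reference
intervals covered by M/=/X/D CIGAR runs, split only at N operations. Indels
are within-exon events, so D and I never open a new block; N is the aligner's
splice signal and always does. Coordinates are 0-based half-open throughout
the package; conversion to 1-based happens only when writing GTF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

from .config import log

# CIGAR operation codes (pysam numeric encoding)
_REF_CONSUME_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_N = 3


@dataclass(frozen=True)
class Junction:
    """A splice junction: the intron between two exonic blocks.

    ``donor_end`` is the exclusive end of the upstream block and
    ``acceptor_start`` the start of the downstream block, so the intron is
    the half-open interval [donor_end, acceptor_start).
    """

    ref_name: str
    donor_end: int
    acceptor_start: int
    strand: str = "?"  # '+', '-', '?'

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError(
                f"intron length < 1: [{self.donor_end}, {self.acceptor_start})"
            )

    @property
    def key(self) -> tuple[int, int]:
        return (self.donor_end, self.acceptor_start)


@dataclass
class SplicedAlignment:
    """One aligned read: exonic blocks plus mate linkage and strand evidence.

    ``strand_tag`` is library/aligner splice-strand evidence (e.g. the XS
    tag), not the alignment orientation flag.
    """

    read_id: str
    ref_name: str
    blocks: list[tuple[int, int]]
    strand_tag: str = "?"
    mate_id: Optional[str] = None
    is_properly_paired: bool = False
    is_read1: bool = True

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"empty block [{s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError("blocks must be sorted with gaps >= 1 bp")
            prev_end = e

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


def blocks_from_cigar(pos: int, cigartuples: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Walk a CIGAR from reference position ``pos`` into exonic blocks.

    M/=/X/D extend the current block; N closes it and skips the intron;
    I/S/H/P consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _REF_CONSUME_IN_BLOCK:
            cur += length
        elif op == _N:
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        # I (1), S (4), H (5), P (6): no reference consumed
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def junctions_of(a: SplicedAlignment) -> list[Junction]:
    """One junction per consecutive block pair, in genomic order."""
    return [
        Junction(a.ref_name, a.blocks[i][1], a.blocks[i + 1][0], a.strand_tag)
        for i in range(len(a.blocks) - 1)
    ]


def _convert(rec: pysam.AlignedSegment, ref_name: str) -> Optional[SplicedAlignment]:
    cig = rec.cigartuples
    if not cig:
        return None
    blocks = blocks_from_cigar(rec.reference_start, cig)
    if not blocks:
        return None
    try:
        strand = rec.get_tag("XS")
    except KeyError:
        strand = "?"
    return SplicedAlignment(
        read_id=rec.query_name,
        ref_name=ref_name,
        blocks=blocks,
        strand_tag=strand if strand in ("+", "-") else "?",
        mate_id=rec.query_name if rec.is_paired else None,
        is_properly_paired=rec.is_proper_pair,
        is_read1=not rec.is_read2,
    )


def read_alignments(
    path: str,
    region: Optional[tuple[str, int, int]] = None,
    min_mapq: int = 0,
) -> Iterator[tuple[str, list[SplicedAlignment]]]:
    """Stream (reference name, alignments) groups from a SAM/BAM file.

    Secondary, supplementary and unmapped records are excluded. Records with
    unparseable CIGARs are skipped with a logged warning. Within each
    reference the alignments are returned sorted by (start, read id), so the
    downstream pipeline is independent of record order in the file.
    """
    per_ref: dict[str, list[SplicedAlignment]] = {}
    skipped = 0
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        ref_order = list(fh.references)
        for rec in fh:  # sequential scan; region filtering needs no index
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if min_mapq and rec.mapping_quality < min_mapq:
                continue
            try:
                a = _convert(rec, rec.reference_name)
            except ValueError:
                a = None
            if a is None:
                skipped += 1
                continue
            if region is not None:
                rname, rstart, rend = region
                if a.ref_name != rname or a.end <= rstart or a.start >= rend:
                    continue
            per_ref.setdefault(a.ref_name, []).append(a)
    if skipped:
        log.warning("skipped %d records with unusable CIGAR", skipped)
    for ref in ref_order:
        if ref in per_ref:
            reads = per_ref[ref]
            reads.sort(key=lambda a: (a.start, a.read_id, not a.is_read1))
            yield ref, reads
    # references present in records but absent from the header (headerless SAM)
    for ref in sorted(set(per_ref) - set(ref_order)):
        reads = per_ref[ref]
        reads.sort(key=lambda a: (a.start, a.read_id, not a.is_read1))
        yield ref, reads
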