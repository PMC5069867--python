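"""Scoring an assembly against a reference annotation.

The matching criterion is exact intron-chain identity: a multi-exon
reference transcript is recovered iff some assembled transcript on the same
reference sequence and compatible strand has the identical ordered list of
donor/acceptor coordinates. Terminal exon ends are unconstrained. Recall is
true positives over expressed reference transcripts; precision is the
fraction of assembled transcripts matching some reference. Single-exon
transcripts, for which the criterion is silent, match by >= 80 % reciprocal
overlap (configurable).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO

import gffutils

from .config import log


@dataclass(frozen=True)
class GtfTranscript:
    transcript_id: str
    ref_name: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


def transcripts_from_gtf(path: str) -> list[GtfTranscript]:
    """Read transcripts (as exon groups) from a GTF file."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    groups: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    skipped = 0
    for ex in db.features_of_type("exon"):
        tids = ex.attributes.get("transcript_id")
        if not tids:
            skipped += 1
            continue
        tid = tids[0]
        groups.setdefault(tid, []).append((ex.start - 1, ex.end))
        meta[tid] = (ex.seqid, ex.strand or ".")
    if skipped:
        log.warning("skipped %d exon records without transcript_id", skipped)
    out = []
    for tid in sorted(groups):
        ref, strand = meta[tid]
        exons = tuple(sorted(groups[tid]))
        out.append(GtfTranscript(tid, ref, strand, exons))
    return out


def _strand_compatible(a: str, b: str) -> bool:
    return a == b or a in ".?" or b in ".?"


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@dataclass
class MatchReport:
    true_positives: int
    n_reference: int
    n_assembled: int
    recall: float
    precision: float
    matched_pairs: list[tuple[str, str]]
    per_bin_recall: dict[str, float] = field(default_factory=dict)

    def to_json(self, out: TextIO) -> None:
        json.dump(
            {
                "true_positives": self.true_positives,
                "n_reference": self.n_reference,
                "n_assembled": self.n_assembled,
                "recall": self.recall,
                "precision": self.precision,
                "per_bin_recall": self.per_bin_recall,
                "matched_pairs": self.matched_pairs,
            },
            out,
            indent=2,
        )

    def to_tsv(self, out: TextIO) -> None:
        out.write("reference_id\tassembled_id\n")
        for r, a in self.matched_pairs:
            out.write(f"{r}\t{a}\n")


def match(
    assembled: Sequence[GtfTranscript] | str,
    reference: Sequence[GtfTranscript] | str,
    expressed_ids: Optional[set[str]] = None,
    abundances: Optional[dict[str, float]] = None,
    min_single_exon_overlap: float = 0.8,
    min_bin_count: int = 20,
) -> MatchReport:
    """Score an assembly against a reference by exact intron-chain matching.

    ``expressed_ids`` restricts the recall denominator to the expressed
    reference transcripts (on simulations: truth abundance > 0); when absent
    every reference transcript counts, which mirrors evaluation on real data
    where the expressed set is unknown. ``abundances`` (per reference
    transcript) additionally produce a recall-vs-expression profile over
    log2-spaced bins, merging bins with fewer than ``min_bin_count``
    members upward.
    """
    if isinstance(assembled, str):
        assembled = transcripts_from_gtf(assembled)
    if isinstance(reference, str):
        reference = transcripts_from_gtf(reference)
    refs = [
        r
        for r in reference
        if expressed_ids is None or r.transcript_id in expressed_ids
    ]

    multi_index: dict[tuple[str, tuple], list[GtfTranscript]] = {}
    single_by_ref: dict[str, list[GtfTranscript]] = {}
    for a in assembled:
        if len(a.exons) >= 2:
            multi_index.setdefault((a.ref_name, a.intron_chain), []).append(a)
        else:
            single_by_ref.setdefault(a.ref_name, []).append(a)

    matched_pairs: list[tuple[str, str]] = []
    matched_refs: set[str] = set()
    matched_asm: set[str] = set()

    def try_match(r: GtfTranscript) -> Optional[GtfTranscript]:
        if len(r.exons) >= 2:
            for a in multi_index.get((r.ref_name, r.intron_chain), []):
                if _strand_compatible(a.strand, r.strand):
                    return a
            return None
        best = None
        best_ov = min_single_exon_overlap
        for a in single_by_ref.get(r.ref_name, []):
            if not _strand_compatible(a.strand, r.strand):
                continue
            ov = _reciprocal_overlap(a.exons[0], r.exons[0])
            if ov >= best_ov:
                best, best_ov = a, ov
        return best

    for r in sorted(refs, key=lambda t: t.transcript_id):
        a = try_match(r)
        if a is not None:
            matched_refs.add(r.transcript_id)
            matched_asm.add(a.transcript_id)
            matched_pairs.append((r.transcript_id, a.transcript_id))
    # precision: every assembled transcript matching any reference transcript
    # (expressed or not) gets credit, even when several certify the same one
    ref_chains: dict[tuple, set[str]] = {}
    for r in reference:
        if len(r.exons) >= 2:
            ref_chains.setdefault((r.ref_name, r.intron_chain), set()).add(r.strand)
    ref_singles = [r for r in reference if len(r.exons) == 1]
    for a in assembled:
        if len(a.exons) >= 2:
            strands = ref_chains.get((a.ref_name, a.intron_chain), ())
            if any(_strand_compatible(a.strand, s) for s in strands):
                matched_asm.add(a.transcript_id)
        else:
            for r in ref_singles:
                if (
                    r.ref_name == a.ref_name
                    and _strand_compatible(a.strand, r.strand)
                    and _reciprocal_overlap(a.exons[0], r.exons[0])
                    >= min_single_exon_overlap
                ):
                    matched_asm.add(a.transcript_id)
                    break

    tp = len(matched_refs)
    recall = tp / len(refs) if refs else 0.0
    precision = len(matched_asm) / len(assembled) if assembled else 0.0

    per_bin: dict[str, float] = {}
    if abundances:
        with_ab = [
            (r, abundances[r.transcript_id])
            for r in refs
            if abundances.get(r.transcript_id, 0) > 0
        ]
        if with_ab:
            binned: dict[int, list[GtfTranscript]] = {}
            for r, ab in with_ab:
                binned.setdefault(int(math.floor(math.log2(ab))), []).append(r)
            merged: list[tuple[int, int, list[GtfTranscript]]] = []
            pending: list[GtfTranscript] = []
            lo = None
            for b in sorted(binned):
                if lo is None:
                    lo = b
                pending.extend(binned[b])
                if len(pending) >= min_bin_count:
                    merged.append((lo, b, pending))
                    pending, lo = [], None
            if pending:
                if merged:
                    plo, _, prev = merged[-1]
                    merged[-1] = (plo, sorted(binned)[-1], prev + pending)
                else:
                    merged.append((lo, sorted(binned)[-1], pending))
            for blo, bhi, members in merged:
                hit = sum(1 for r in members if r.transcript_id in matched_refs)
                per_bin[f"2^{blo}..2^{bhi + 1}"] = hit / len(members)

    return MatchReport(
        true_positives=tp,
        n_reference=len(refs),
        n_assembled=len(assembled),
        recall=recall,
        precision=precision,
        matched_pairs=matched_pairs,
        per_bin_recall=per_bin,
    )
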