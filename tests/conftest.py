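"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np
import pytest

from splicecomb import LocusReads, SplicedAlignment, SplicingGraph


# ------------------------------------------------------ independent oracles


@lru_cache(maxsize=None)
def _assignment_space(n: int, m: int) -> np.ndarray:
    return np.array(list(itertools.product(range(m), repeat=n)), dtype=np.int64)


def brute_force_binpack(items, bins):
    """Exhaustive minimum of the quadratic assignment objective.

    Enumerates every surjective assignment of n items to m bins and returns
    the minimal sum of squared bin residuals. Vectorized but otherwise a
    direct transcription of the definition; independent of the package's
    branch-and-bound solver.
    """
    items = np.asarray(items)
    bins = np.asarray(bins)
    n, m = len(items), len(bins)
    space = _assignment_space(n, m)
    onehot = space[:, :, None] == np.arange(m)[None, None, :]
    loads = (onehot * items[None, :, None]).sum(axis=1)
    feasible = (onehot.any(axis=1)).all(axis=1)
    z = ((bins[None, :] - loads) ** 2).sum(axis=1)
    z = np.where(feasible, z, np.iinfo(np.int64).max)
    return int(z.min())


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_blocks_oracle(pos: int, cigar: str):
    """Test-local CIGAR walk (regex-based), independent of alignments_io."""
    blocks = []
    start = cur = pos
    for num, op in _CIGAR_RE.findall(cigar):
        num = int(num)
        if op in "MD=X":
            cur += num
        elif op == "N":
            if cur > start:
                blocks.append((start, cur))
            cur += num
            start = cur
    if cur > start:
        blocks.append((start, cur))
    return blocks


def parse_sam_fragments(sam_lines):
    """Group SAM body lines into fragments: qname -> list of block lists."""
    frags = {}
    for line in sam_lines:
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        qname, pos, cigar = f[0], int(f[3]) - 1, f[5]
        frags.setdefault(qname, []).append(cigar_blocks_oracle(pos, cigar))
    return frags


# ----------------------------------------------------------- graph builders


def make_alignment(ref, blocks, read_id="r", strand="+", mate=False, is_read1=True):
    return SplicedAlignment(
        read_id=read_id,
        ref_name=ref,
        blocks=list(blocks),
        strand_tag=strand,
        mate_id=read_id if mate else None,
        is_properly_paired=mate,
        is_read1=is_read1,
    )


def graph_from_parts(
    exons, junctions, pair_support=None, coverage=30, locus_id="t", strand="+"
):
    """Construct a SplicingGraph directly from exon intervals + junctions.

    ``coverage`` may be a scalar or one value per exon interval.
    """
    offset = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    cov = np.zeros(end - offset, dtype=np.int64)
    covs = [coverage] * len(exons) if np.isscalar(coverage) else list(coverage)
    for (s, e), c in zip(exons, covs):
        cov[s - offset : e - offset] = c
    return SplicingGraph(
        locus_id=locus_id,
        ref_name="chrT",
        strand=strand,
        offset=offset,
        cov=cov,
        junctions=dict(junctions),
        fragments=(),
        pair_support_override=pair_support,
    )


@pytest.fixture
def two_exon_locus():
    """Seven spliced reads over a two-exon transcript, plus body reads."""
    reads = []
    for i in range(7):
        reads.append(
            make_alignment("chrT", [(100 + i, 150), (250, 280 + i)], f"j{i}")
        )
    for i in range(5):
        reads.append(make_alignment("chrT", [(100 + 2 * i, 140 + 2 * i)], f"b{i}"))
    return LocusReads("chrT", "+", reads)
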