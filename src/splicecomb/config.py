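"""Assembly parameters and logging setup.

All thresholds that shape the assembly are policy, not constants: every one of
them is surfaced here and on the command line. Defaults reflect a typical
strand-specific paired-end short-read library (100 bp reads, ~300 bp
fragments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger("splicecomb")


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="[%(levelname)s] %(name)s: %(message)s"
    )


@dataclass
class AssemblyConfig:
    """Tunable parameters for the whole pipeline.

    Attributes
    ----------
    min_junction_reads:
        Minimum spliced reads required for a junction to become a splicing
        graph edge. 1 preserves recall of lowly expressed transcripts.
    min_mapq:
        Minimum mapping quality; 0 disables the filter.
    max_gap:
        Coverage islands on the same strand closer than this (bp) are
        clustered into one locus even without mate links or shared junctions.
    max_fill:
        Largest coverage gap (bp) that mate pairs may bridge when repairing a
        fragmented exon; roughly an upper bound on the fragment length.
    min_pairs:
        Mate pairs required both to repair a fragmented exon and to promote a
        junction-graph edge to weight 2.
    window:
        Sliding-window width (bp) for the pseudo-exon correction.
    drop_ratio:
        A low-coverage run is removed when its coverage falls below
        ``drop_ratio`` x the flanking coverage.
    promote_zero_weight:
        Whether mate-pair promotion may raise a bin-packing weight-0 edge to
        2 (the literal reading of the weighting rule); when False only
        weight-1 edges are promoted.
    exact_assignment_limit:
        The in/out-edge assignment is solved exactly when the number of
        candidate assignments (bins**items) is at most this; otherwise the
        local-search heuristic is used.
    min_single_exon_len / min_single_exon_depth:
        Floors for emitting a transcript from a junction-free locus.
    min_frac:
        Locus-relative expression filter; transcripts below
        ``min_frac`` x the locus maximum are dropped. 0 keeps everything
        (the default: no filtering).
    min_abs_cov:
        Optional absolute seed-coverage filter (0 disables); alternative to
        the relative filter.
    read_length:
        Read length used by the expression estimator's positional model.
    """

    min_junction_reads: int = 1
    min_mapq: int = 0
    max_gap: int = 50
    max_fill: int = 400
    min_pairs: int = 2
    window: int = 50
    drop_ratio: float = 0.1
    promote_zero_weight: bool = True
    exact_assignment_limit: int = 10**6
    min_single_exon_len: int = 200
    min_single_exon_depth: float = 2.0
    min_frac: float = 0.0
    min_abs_cov: float = 0.0
    read_length: int = 100


DEFAULT_CONFIG = AssemblyConfig()
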