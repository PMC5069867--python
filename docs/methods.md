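# Methods

This note records the model splicecomb implements, the parameters that
matter, the numerical choices behind them, and what the synthetic studies do
and do not demonstrate.

## Model and assumptions

splicecomb assembles transcripts per gene locus from spliced alignments
alone (no annotation). Its core assumptions:

* every expressed junction is witnessed by at least one spliced read
  (`min_junction_reads`, default 1 — the floor is kept minimal to preserve
  recall of lowly expressed transcripts);
* read coverage of a junction is roughly proportional to the summed
  abundance of the isoforms containing it, so balancing in- against
  out-junction coverage at an exon (the quadratic assignment below) is
  informative about which junction pairs co-occur;
* fragments regularly bridge consecutive junctions, so mate pairs can
  arbitrate where coverage balance is ambiguous or degenerate.

Coordinates are 0-based half-open everywhere internally; GTF output converts
to 1-based inclusive at the boundary. Duplicate reads are not collapsed:
junction coverage is defined as the count of spanning reads. Indel CIGAR
operations (I/D) never split exonic blocks; only N does, because N is the
aligner's splice signal while indels are within-exon events. Soft-clip
evidence for exon boundaries is not used.

## Pipeline and parameters

**Locus clustering** (`max_gap`, default 50 bp). Reads sharing exonic-block
overlap, a junction, or a mate link are clustered transitively; coverage
islands closer than `max_gap` merge to tolerate micro-gaps. Overlap is
block-level, not span-level, so a read lying wholly inside another read's
intron is not pulled in by the spliced read alone. Loci with conflicting
strand tags are split by strand; untagged reads follow the locus strand when
unambiguous, otherwise they contribute to both strand loci.

**Graph construction.** Node boundaries are exactly the junction
donor/acceptor sites plus coverage-island ends; a node may be a partial
exon. Edge coverage is the spanning-read count. Per-fragment junction chains
are recorded; a fragment supports the incident junction pair (e1, e2) when
its reads span both junctions (one read spanning both counts — it is
strictly stronger evidence than a mate pair). Flanking-only mate placement
is deliberately not counted: when the shared exon has alternative
out-junctions, a mate lying beyond the exon does not identify which
junction it took, so span-based counting is the conservative, exactly
testable choice.

**Fragmented-exon repair** (`max_fill` 400 bp ~ a fragment-length upper
bound; `min_pairs` 2, the same threshold used for weight promotion). Two
neighbouring islands with no junction between them merge when at least
`min_pairs` fragments place one read on each and the gap is at most
`max_fill`; the gap is filled with the rounded mean of the flanking island
coverages. Applied to a fixpoint (transitive merging); a gap flanked or
spanned by a recorded junction is a real intron and is never filled. The
operator is idempotent.

**Pseudo-exon correction** (`window` 50 bp, `drop_ratio` 0.1; both are
policy, not constants, and are CLI-exposed). One flank-relative statistic is
applied at two granularities:

* *within a node* longer than 2x`window`: a candidate low run is detected on
  the window-smoothed coverage (below `drop_ratio` x the profile maximum),
  its boundaries refined to the per-base coverage step using the midpoint
  between run and flank coverage (robust to single-base noise spikes), and
  confirmed when its mean is below `drop_ratio` x the minimum flanking
  window mean. Interior runs split the node; terminal runs trim it, but a
  node end that anchors a junction is never trimmed (no edge loses its
  coverage flank);
* *across nodes*: a node with no incident splice edge, inside a locus that
  has splice edges, is discarded when its mean coverage falls below
  `drop_ratio` x the mean coverage of the nearest splice-attached nodes.

The second rule is this package's reconstruction choice: because node
boundaries sit exactly at donor/acceptor sites, reads wrongly mapped into a
spliced intron materialize as a separate junction-free node between two real
exons rather than as an internal low run, and the same flank-relative
threshold applies at node granularity. Junction-free loci (candidate
single-exon genes) have no exonic reference coverage and are left alone.
Both applications re-derive nodes from the cleaned coverage vector, which
makes the operator idempotent by construction.

**Junction-graph weighting.** At each interior exon the in-junctions are
items sized by coverage and the out-junctions bins with coverage capacities
(roles swap when out-junctions outnumber in-junctions; the model is
symmetric under edge-direction reversal). The assignment minimizing the sum
of squared bin residuals, subject to each item placed once and each bin
receiving at least one item, is solved by branch and bound with items in
decreasing size order and the admissible bound "sum of squared overfills so
far" (bin loads only grow, so overfill penalties are irrevocable). Exact
mode runs while `bins**items` is at most `exact_assignment_limit` (1e6 —
real exons have few junctions, so the heuristic path is a safety valve);
the heuristic is greedy placement (better of best-fit-decreasing and
size-ordered first fit) plus first-improvement local search over single-item
moves and pairwise swaps, so its objective never exceeds the first-fit
baseline. Ties among equal-objective optima are broken toward the
lexicographically smallest assignment with items and bins each ordered by
(coverage descending, genomic coordinate ascending) — a platform-independent
determinism guarantee.

**Paired-end promotion** (`min_pairs` 2). An edge whose junction pair is
supported by at least `min_pairs` fragments is set to weight 2 regardless of
its assignment weight — including weight 0, the literal reading of
"replace"; `promote_zero_weight=False` restricts promotion to weight-1
edges for users who prefer the conservative reading. Promotion never
decreases a weight and is idempotent.

**Path extraction.** Seeds are chosen among junctions not yet covered by any
path, heaviest first (tie: smaller coordinate). Extension is bidirectional,
taking at each step an edge of maximal priority (2 > 1; 0 never taken; a
node whose out-edges are all weight 0 terminates extension, since weight-0
edges are untraversable by definition). Ties prefer the heavier neighbor,
then the smaller coordinate. Paths may share junctions; duplicates collapse
by intron chain. Allowing seeds only from uncovered junctions (rather than
junctions not interior to any path) is the documented reading of the
exclusion rule. Terminal exons extend through genomically contiguous
(partial-exon) nodes to the coverage-supported ends.

**Single-exon loci** (`min_single_exon_len` 200 bp, `min_single_exon_depth`
2x). Junction-free loci emit one transcript per island passing both floors.
Within junction-containing loci, junction-free leftovers are never emitted —
they are either pseudo-exon remnants or unspliced background.

**Expression** (`read_length`, default 100 bp). A junction is spannable from
`read_length - 1` start positions, so `seed_coverage / (read_length - 1)` is
a depth-equivalent and `FPKM = 1e9 * seed_coverage / ((read_length - 1) *
total_mapped_reads)`; the estimate is length-independent by construction.
Single-exon transcripts substitute mean depth / read length as the
depth-equivalent. Scale equivariance holds exactly: multiplying all counts
and the library size by k leaves FPKM unchanged. This estimator is a
reconstruction committed behind one function so alternatives are drop-ins;
seeds are unique per path by construction, so redistribution of shared seed
coverage never arises.

**Filtering** (`min_frac`, default 0 = keep everything). The filter is
locus-relative (fraction of the locus's maximum expression) because a single
scalar that sweeps the precision/recall trade-off is the intended use; an
absolute floor (`min_abs_cov`) is available as an alternative. MAPQ
filtering is off by default (`min_mapq` 0) and configurable.

## Evaluation

A reference transcript counts as recovered iff an assembled transcript on
the same reference sequence and compatible strand has the identical intron
chain; terminal exon ends are unconstrained. An unknown strand ('.')
matches either strand, since unspliced single-exon loci carry no splice
strand evidence. Single-exon transcripts match by >= 80 % reciprocal overlap
(a familiar fuzziness convention; configurable). Recall divides by the
expressed reference set when truth abundances are known, else by all
reference transcripts (the report says which). Precision credits every
assembled transcript matching some reference, even when several certify the
same one. The recall-vs-expression profile uses log2-spaced truth-abundance
bins, merging bins with fewer than 20 members upward.

## Synthetic data: what it shows and what it does not

The generator produces multi-isoform loci sharing exons, spliced paired-end
reads with normal fragment lengths (default 300 +- 25 bp, 100 bp reads),
coverage proportional to molar abundance x transcript length, coverage gaps
at low depth, and uniform intronic noise reads. `bridge_pairs` adds a stated
number of mate pairs centered on each consecutive junction pair of every
isoform — making "fragments bridge shared exons" a guaranteed property of
the library rather than a tail event of the fragment-length distribution;
with ~100 bp shared exons, 300 bp fragments and 100 bp reads, the window in
which a random fragment spans both junctions is only a few bases, which is
a statement about that geometry, not about the assembler. The study suites
use 3-6 exons per locus (terminal exons 150-300 bp, internal 80-150 bp,
introns 120-500 bp), 1-3 isoforms built from exon-skipping motifs at
distinct abundances (100 %, 30 %, 10 % of full depth), 50 loci at 100x for
the recovery study, plus intronic noise at 5 % of exonic depth and one 5x
isoform for the degraded study — sizes at which the full suite runs in
seconds on one CPU.

Not modeled: sequencing errors, positional/GC bias, multi-mapping,
annotation-guided assembly, intron retention quantification. Perfect
recovery on these fixtures therefore demonstrates the combinatorial core —
graph construction, weighting, extraction, and the corrections — not
robustness to aligner artifacts on real libraries.

## Degenerate and edge cases

* Equal-coverage diamonds make the assignment objective degenerate (two
  optima with equal cost); the lexicographic tie-break picks the
  coordinate-parallel pairing deterministically, and mate-pair promotion
  overrides it whenever fragment evidence exists — the designed division of
  labor between the two evidence sources.
* A junction whose coverage flank was removed by a correction (cannot occur
  through the shipped operators, which protect anchored ends) would be
  dropped from the edge set with a debug log rather than crash.
* Loci with zero junctions skip the junction graph entirely.
* Unstranded data degrade gracefully: strand is reported as '.' and the
  evaluator treats it as compatible with either strand.

## Known limitations

* An exon whose in-junction genuinely feeds two out-junctions (isoforms
  diverging after a shared junction) cannot be expressed by the one-to-one
  assignment; recovery there relies entirely on mate-pair promotion, so
  libraries whose fragments rarely bridge shared exons will lose such
  isoforms.
* The expression estimator ignores all coverage except the seed junction;
  it is rank-faithful on the fixtures but makes no claim of unbiasedness.
* Single-CPU by design at this scale; no CRAM, no long reads.
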