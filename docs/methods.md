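# Methods

This note records the models, conventions and design choices behind
lecdup, in the spirit of a methods appendix: enough detail to judge
what the computations mean and where their limits are.

## Coordinates and gene rank

All internal coordinates are 0-based half-open; GFF3 (1-based closed)
and BED convert at the I/O boundary.  Every gene receives a *rank*,
its 0-based order index along its chromosome by ascending start
(ties: ascending end, then gene id).  All locality notions — tandem
spacers, synteny gaps, block-merge distances, quota depth — are
counted in ranks, not base pairs, because the classification
parameters of this workflow (10 intervening genes for tandem arrays,
20-gene chain gaps, 350-gene merges) are gene-count parameters.
Strand is stored but never flipped on read; orientation logic lives in
the duplicate classifier.

Similarity tables are BLAST outfmt-6 column order.  The 0.5–2
length-ratio filter needs sequence lengths, which plain 12-column
outfmt 6 lacks; the reader accepts the common `std qlen slen`
13/14-column dialect and leaves lengths absent otherwise, in which
case length-window filtering raises rather than guessing.

## Synteny model

An anchor is a homologous gene pair placed at $(r_a, r_b)$ in rank
space.  A block is a chain with strictly increasing $r_a$ and strictly
monotone $r_b$ (increasing = "same" orientation, decreasing =
"inverted"), successive-anchor gaps at most `max_gap` = 20 on both
axes, scored one point per anchor minus `gap_penalty` = 0.05 per gap
gene.  The published workflow ran DAGchainer inside SynMap, whose
exact scoring is not restated anywhere usable; this linear scoring is
adopted because it is simple, fully specified, and testable against
exhaustive chain enumeration (the suite verifies exact agreement on
hundreds of random instances).  Chains are extracted greedily (best
score; ties prefer "same" orientation, then the earliest chain), each
anchor used once, chains shorter than `min_anchors` = 5 discarded.
Blocks whose facing ends are within 350 ranks on both axes merge, and
merging iterates to fixpoint (the single-pass alternative is
order-dependent).  A per-gene syntenic-depth cap (`max_depth` = 3,
greedy by block score) stands in for LP-based quota filtering:
deterministic, testable, and adequate at simulated depths.

Self-comparison drops identity anchors, normalizes pairs as unordered,
and additionally excludes same-chromosome anchors within 40 ranks of
the diagonal.  That band is tandem-array structure: large arrays
otherwise chain into spurious intra-array "blocks" whose anchors would
be reported as ohnologs.  Tandem runs that hit the same partner gene
are *not* pre-collapsed to a lowest-rank representative: the chain
DP's strict monotonicity already admits only one member per run, and
it picks the member that continues the diagonal, which is more
reliable than any rank-based rule when a recent duplicate happens to
precede the syntenic gene.  (An explicit collapse remains available
via `tandem_collapse_window` for data where pre-collapsing is wanted.)

Blocks are dated by the median NG86 Ks of their anchors against
user-supplied epoch bins (defaults alpha < 1.0 ≤ beta < 2.2 ≤ gamma).
Absolute Ks scales are lineage- and calibration-dependent, so the bins
are parameters, not constants, and reports carry the epoch label next
to the median Ks rather than in place of it.

## Duplicate modes

*Tandem arrays* are connected components of the graph joining
same-chromosome homolog pairs with ≤ `max_spacers` = 10 intervening
genes — components, not consecutive runs, so two members ten spacers
apart bridged by a middle member form one array.  Adjacent-pair
orientation uses strand geometry only (parallel strands =
head-to-tail, the unequal-crossing-over signature); shared-promoter
inference is out of scope.

*GTD* is the residual mode.  A gene's homolog is "explained" if it is
reachable from the gene through the union of tandem and ohnolog edges;
the closest unexplained homolog at $e \le 10^{-30}$ becomes the
transposition partner.  Reachability (rather than a pairwise check) is
essential: a tandem copy of a retained ohnolog sees its parent's WGD
partner as an unexplained strong homolog under a pairwise rule, and
every such family would yield a false transposition call.  The strict
e-value threshold — two orders tighter in log-space than homology
filtering — encodes the expectation that scoreable transposition
partners are recent duplicates.

*Polarization* of a GTD pair votes over four asymmetries of the novel
copy (more indel events, longer maximum indel, shorter CDS, shorter
mean exon), counting a gap run in a sequence as a deletion in that
sequence.  Attribution of indels from a pairwise alignment is
convention, not inference — without an outgroup an insertion in one
copy is indistinguishable from a deletion in the other — so the vote
is a majority over criteria with ties left unresolved, and the
simulator degrades novel copies by truncation/deletion to match the
convention.  When exon structure is absent the exon criterion
abstains and CDS length carries the length evidence.

*TD-α* marks tandem duplication layered on polyploidy.  The default
semantics is array-level: every member of a tandem array containing an
ohnolog-pair participant (of the requested epoch) is TD-α — the copies
belonging to a tandem-duplicated ohnolog count along with the ohnolog
itself.  A strict gene-level intersection (`semantics="gene"`) is also
provided, but note it depends on *which* array member carries the
syntenic anchor, an assignment that is genuinely unidentifiable from
pairwise data when several members are equidistant from the partner;
the array-level set is invariant to that choice.

Per-gene labels are non-exclusive; the Venn partition over
{tandem, ohnolog, gtd} covers exactly the non-singleton genes.

## NG86 Ka/Ks

Codon alignments are cleaned by removing columns with a gap, a stop
codon, or a non-ACGT character in either sequence; frame violations
are hard errors.  Site counting assigns each codon synonymous and
nonsynonymous site fractions from its nine single-nucleotide
neighbours, with mutations creating stop codons counted as
nonsynonymous so that $N + S = 3$ per codon exactly.  Differences
between codons are averaged over all substitution orderings, with
pathways passing through a stop codon excluded and the average
renormalized over valid pathways (if no ordering avoids stops, the
unfiltered average is used so differences are not lost).  Proportions
are Jukes–Cantor corrected; a non-positive log argument (saturation,
$p \ge 3/4$) leaves the rate NaN with an explicit flag, never a silent
zero, and ω is undefined when Ks = 0.  Note the degenerate consequence
for very short alignments: a single synonymous difference in a
one-codon alignment has $p_s = 3$ and is reported saturated.

Per-mode aggregation assigns each pair one mode (ohnolog pairs with a
TD-α member → td_alpha; then tandem, ohnolog, gtd) and reports both
the ratio of mode means (mean Ka / mean Ks — the convention behind
tabulated per-mode values) and the mean of per-pair ratios.  Rounding
(half-up: percentages to integers, array means to one decimal, Ka/Ks
to two decimals) happens only at report time.

The standard nuclear code (table 1) is assumed throughout.  A small
codon-aware global aligner (whole-codon gaps, +3/−3 match scoring,
linear gap penalty 4) is included for fixtures and simulator output;
real analyses are expected to consume externally aligned CDS.

## Enrichment and summary statistics

Ohnolog enrichment uses a one-sided (greater) Fisher's exact test —
over-retention is the stated hypothesis — on a 2×2 table whose
background cells exclude the target genes, avoiding double-counting.
The suite verifies the p-value against exact hypergeometric sums for
every table with total count ≤ 60.  Retention scores are percentages
of reference family members retained; pooled (Σ) rows sum raw counts
across species before recomputing percentages.  No multiple-testing
correction is applied across species, matching the workflow this
mirrors.

## Simulator

The generator defines the study conditions; its defaults are fixed,
not tuned.  Defaults: 500 ancestral genes on 5 chromosomes, CDS
lengths 3 × Uniform[100, 500] codons with 1–5 exons; one WGD round
with per-copy retention 0.6 at age 0.4; tandem arrays at 2 events per
100 genes (geometric copy counts, insertion 0–2 spacers downstream,
10 % inverted) at age 0.25; transpositions at 1 per 100 genes at age
0.15, the novel copy truncated with probability 0.7 and hit by
Poisson(1.5) codon deletions, landing ≥ 50 ranks away or on another
chromosome.  Ages are in units of the substitution clock (0.8
proposals/site/unit), so a pair split at age τ expects synonymous
divergence ≈ 2 × 0.8 × τ — about 0.64 for WGD pairs and 0.24–0.4 for
local duplicates, far from saturation.  WGD ages separate cleanly
from local-event ages, which is what lets a strict e-value threshold
separate transposition partners from old polyploids, as in real
screens.

Sequence evolution is proposal/acceptance per site: proposals arrive
at rate × max(1, ω); synonymous proposals are accepted with
probability 1/max(1, ω) and nonsynonymous with ω/max(1, ω); stop
codons are never created.  The synonymous clock is therefore
ω-independent while realized Ka/Ks tracks ω, including ω > 1.  Each
duplication sets both partners' ω to the mode's value going forward
(tandem 1.2, ohnolog 1.1, gtd 0.9, background 1.0), so TD-α pairs —
ohnolog pairs whose recent history is tandem — land between the
tandem and ohnolog values, reproducing the expected ordering tandem ≥
TD-α ≥ ohnolog > GTD.  Because mutations to stop codons are rejected
by the process but counted as nonsynonymous opportunity by NG86, the
estimator carries a ~5–8 % downward bias on ω under these conditions
(neutral recovery ≈ 0.92–0.94); the bias is shared across modes and
does not disturb the contrasts.

Truth labels: ohnolog and GTD truth are event-based (surviving WGD
pairs; transposition events).  Tandem truth is configurational —
family members within ≤ 10 intervening genes in the *final* gene
order — because a transposed copy that lands beside a relative is
genuinely a proximal duplicate in the resulting genome, and real
screens observe exactly such GTD copies inside tandem clusters.
TD-α truth is array-level, mirroring the classifier definition.

The emitted hit table is derived from the true families (e-value
decaying with lineage divergence age, plus log-normal noise; identity
computed from the sequences), not from running an aligner: hits exist
exactly for detectable homologs.  What the simulator does *not*
emulate: intergenic/TE sequence, unannotated or mis-annotated gene
models, segmental (sub-chromosomal) duplications, homology detection
noise (spurious cross-family hits), gene loss outside fractionation,
and codon-usage or transition/transversion structure (the proposal
kernel is uniform).  Passing recovery tests therefore demonstrates the
*logic* of the classifiers under known history, not robustness to
annotation artefacts in real genomes.

## Problem sizes and determinism

Validation runs use 5–10 simulated genomes of ~800 genes each,
200-instance oracle batches, 100 NG86 oracle pairs of 300 codons and
200 neutral pairs — sizes chosen so the whole suite and the
acceptance script each complete in minutes on one CPU while leaving
every statistic well-resolved.  All randomness flows from explicit
seeds (numpy `default_rng`); identical configurations are
byte-identical, and the acceptance script derives every sub-seed from
its single `--seed` argument.

## Known limitations

Chain extraction is greedy per chromosome pair, not a global optimum
over block sets; quota filtering is greedy rather than LP-optimal;
the within-genome diagonal exclusion (40 ranks) would also mask a
genuine intra-chromosomal proximal WGD segment; GTD polarization is
convention-bound without an outgroup; NG86 is a counting method —
for publication-grade ω on deep divergences a codon-model estimator
should be layered on the same pair lists (the result dataclass
carries a method tag for that purpose).
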