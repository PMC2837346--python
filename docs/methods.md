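# Methods

This note documents the models and procedures `mirkit` implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical/design choices made where the design was genuinely open.

## Tag processing

Reads are 3'-adapter-ligated small RNA inserts sequenced with read-through
into the adapter. Trimming is exact-prefix search: the insert is the read
prefix before the leftmost occurrence of the first `min_overlap` (default
5) adapter bases. There is no mismatch-tolerant adapter model; exactness
keeps the behaviour auditable, and reads whose adapter is corrupted by a
sequencing error simply fail to trim and are later removed by the length
window. Identical inserts collapse into unique tags with copy numbers
(order: descending count, then sequence). Admission requires copy number
≥ 2 — singleton reads are overwhelmingly sequencing errors or ligation
noise — and length in [17, 27] nt. The 17 nt floor sits directly above the
16-nt mature-length exclusion applied later to candidates; the bounds are
package defaults, configurable per call.

## Exact alignment

All placements are perfect matches, consistent with the stringency of the
rest of the pipeline. The index stores every reference k-mer (k = 12,
below the shortest admissible tag) and verifies each seed hit by direct
string comparison, so the hit set provably equals a naive scan's (this is
tested against one). Precursor and transcriptome searches are plus-strand
only, because small RNA reads are sense to the mature miRNA; genome and
rRNA searches cover both strands. Tags with more than `max_hits` (10)
genomic placements are flagged multimapped and excluded from candidate
calling — repeat-derived tags would otherwise spawn arbitrary numbers of
false loci.

## Known-miRNA annotation

A tag hitting a known precursor is assigned to the mature or star arm when
both of its ends lie within `arm_tolerance` = 4 nt of that arm's annotated
ends; anything else (loop-centred, straddling) counts toward the hairpin
region. The 4 nt window covers the isomiR end heterogeneity actually
observed in deep-sequencing data while keeping arm assignments unambiguous
for precursors with ≥ 8 nt loops. IsomiR offsets are signed differences
(tag end − annotated end) recorded separately for the 5' and 3' ends; the
(0, 0) isomiR is the annotated mature sequence. Arm ratios are computed
from counts summed over all isomiRs of an arm, and classed star-dominant
(< 0.75), equivalent (0.75–2.2, both edges inclusive) or mature-dominant
(> 2.2); a zero star count gives an undefined ratio rather than a
pseudocount, because a ratio against an unobserved arm is not meaningful.
Presence in a library means ≥ 1 assigned arm read after the admission
filters.

## Hairpin folding

The folder is a weighted Nussinov dynamic program: maximise the sum of
pair weights (GC 3, AU 2, GU 1; lone pairs allowed; hairpin loops ≥ 3 nt)
over nested structures. It deliberately replaces nearest-neighbour
thermodynamics: the pipeline only ever uses the fold as a binary hairpin
gate, and a base-pair-maximisation DP can be verified exactly against
exhaustive structure enumeration, which the test suite does. The traceback
is deterministic (pairing preferred over leaving a base unpaired; smallest
partner index on ties). `is_hairpin` requires ≥ 16 pairs, ≥ 50 % of bases
paired and exactly one terminal loop — a 22 nt mature product needs a stem
of at least its own length, and the single-terminal-loop rule is what
separates genuine stem-loops from the multi-branch optima of random
sequence (≥ 95 % of dinucleotide-shuffled precursor-length controls fail
it).

Candidate evaluation folds **precursor-sized subwindows**, not the full
flanked windows. The search region around a genomic tag hit is delimited
by two windows (short 20 nt flank upstream + long 70 nt flank downstream
for the tag-on-5'-arm hypothesis, mirrored for the 3'-arm hypothesis,
strand-aware). But the optimal structure of a ~110 nt window is dominated
by spurious pairings in the unrelated flanking sequence, which add side
stem-loops and would fail even perfect planted hairpins against the
single-loop criterion. Since a pre-miRNA is at most ~65 nt, the gate
instead folds subwindows of 46–67 nt (step 3) anchored 3 nt outside the
tag's precursor-proximal end, and passes if any subwindow satisfies
`is_hairpin`. For a true hairpin the best-fitting subwindow contains the
full stem plus ≤ 5 nt of flanking junk — too short to fold into a
competing stem-loop — while random sequence still fails on the pair count
and loop criteria.

## SCFG classifier

A pre-miRNA hairpin is modelled as a stem interrupted by symmetric and
asymmetric bulges with a terminal loop. The grammar has five nonterminals
(S, Stem, SymBulge, AsymBulge, Loop) and 76 productions: pair emissions
`Stem → a Stem b` and `Stem → a SymBulge b` over all 16 base combinations
(so every sequence has nonzero probability), one-sided bulge emissions,
loop emissions, and non-emitting transitions back to the stem. Training is
fully supervised: each known hairpin's dot-bracket structure parses
deterministically into a unique state path (paired columns → Stem,
unpaired-on-both-ends columns → SymBulge, one-sided → AsymBulge, the
terminal unpaired run → Loop), production probabilities are pseudocount-
smoothed usage frequencies (smoothing 1), and multiloop structures are
rejected by name. Scoring is the inside algorithm in natural-log space —
because every production carries at most one nonterminal the DP is
O(L²·productions) with no bifurcation split — and the score is normalised
per nucleotide. The pass cutoff is the 95 %-specificity quantile of
normalised scores of dinucleotide-shuffled negatives (Altschul–Erickson
Euler-walk shuffling, which preserves dinucleotide counts and therefore
composition and stacking statistics); the original tool's cutoff is not
published, so a specificity quantile is the principled replacement and is
configurable.

## Novel discovery

The cascade order is fixed: known precursors, then transcriptome, then
genome; a tag matching an earlier reference never reaches a later one, and
unmatched tags are dropped. Genome-residual tags (excluding multimappers)
merge into loci when their placements overlap by ≥ 1 nt on the same
strand, so isomiR ladders produce a single candidate whose mature sequence
is the most abundant member tag. Each locus is gated on the hairpin fold
and on the SCFG score of the best hairpin subwindow. Post-filters:
perfect-match rRNA hits (exact match is the operationalisation of "likely
rRNA degradation product", consistent with the pipeline's exact-match
ethos); exon overhang > 2 nt, measured strand-agnostically against all
annotated exons; mature length exactly 16 nt; and, to be *named* rather
than remain a passing candidate, a total read count across libraries
strictly greater than 5 (the threshold is interpreted as summed across
libraries; a per-library variant is one parameter away). Candidate ids are
assigned in a deterministic order (descending total count, then genomic
coordinate). Cross-library tallies report, per library, candidates unique
to it and candidates shared with ≥ 1 other library; unique + shared =
total by construction.

A planted hairpin yields up to two named candidates — one from mature-arm
tags and one from star-arm tags — because the two arms map to disjoint
genomic intervals and each is an independently observed novel sequence.
Recovery metrics therefore ask whether *some* named candidate overlaps the
planted precursor.

## Genomic context

Internally everything is 0-based half-open; GFF3 I/O converts to and from
1-based closed coordinates. UTRs are derived on the fly: exonic sequence
between the transcript boundary and the CDS boundary, mirrored on the
minus strand; coding exons, UTRs and introns partition the transcript
interval exactly (property-tested). Per overlapping transcript the feature
with maximal overlap wins; across transcripts precedence is
mirtron_typical > mirtron_atypical > exon > 5'UTR > 3'UTR > intron >
promoter > intergenic, with ties broken by transcript id. Mirtron typing
compares precursor ends to intron boundaries exactly (tolerance 0,
configurable): both ends anchored → typical, exactly one → atypical.
Promoters are 1000 nt upstream of the TSS, strand-aware — "promoter" has
no coordinate definition in annotation, so a conventional fixed window is
used.

## Expression profiles

Expression is the relative proportion count / total reads of the library
(known miRNAs use mature + star counts; candidates their locus counts).
Libraries (columns) are the clustered entities. The metric is centred
Pearson correlation distance d = 1 − r (zero-variance profiles get
distance 1 with a warning); linkage is unweighted average (UPGMA), which
guarantees monotone merge heights, with a deterministic tie-break (the
lexicographically smallest pair of cluster keys merges first). The
implementation is a direct agglomerator checked against scipy's linkage
heights; the dendrogram exports to Newick and round-trips through
scikit-bio's reader. Top-N reports rank rows per library by proportion
(ties by id) and also return the non-redundant union across libraries.

## Synthetic data

The generator builds one chromosome (default 300 kb, uniform ACGT) laid
out left to right as gap–gene–gap–…, with 30 three-to-five-exon coding
genes (exons 120–250 nt, introns 150–400 nt, UTRs 30–80 nt). Planted
hairpins have a 20–24 nt 5' arm, an 8–15 nt loop and a 3' arm that
reverse-complements the 5' arm with 1–2 mismatches. At least one mismatch
is required so that the mature tag is not the exact reverse complement of
the star arm; with a perfect inverted repeat every mature read would also
perfect-match the minus strand at the star arm and each planted locus
would produce a duplicate phantom candidate. Every planted precursor (and
its 5 nt-flanked registry version) is verified to pass `is_hairpin` at
generation time and resampled otherwise, and precursors containing the
first 5 adapter bases (either strand) are rejected so adapter trimming
cannot truncate genuine mature reads. Default planting: 24 known miRNAs
and 16 novel miRNAs rotating through intron / intergenic / promoter
contexts, 2 typical mirtrons (precursor = intron), 2 atypical mirtrons
(one end at a splice site), 2 intergenic rRNA genes and 4 mRNA-decoy
windows in fully coding exons. Known precursors are registered with 5 nt
flanks so that ±2 nt isomiR ends remain inside the registry sequence.

Reads are sampled per library: a locus by configured weights, an arm by
the locus's mature:star ratio (drawn once per reference set from the grid
0.03 / 0.3 / 1 / 10 / 100 / 2000, spanning star-dominant to extreme
mature-dominant), end offsets from the isomiR table (default: 30 % of
reads with a nonzero 3' offset vs 5 % with a nonzero 5' offset, matching
the field's observation that 3' heterogeneity dominates), per-base
substitution errors at 10⁻³, 3' adapter read-through to a 36 nt read with
uniform 'I' qualities, plus 5 % uniform-random singleton noise inserts.
Every read carries a ground-truth origin record. The default study design
is 12 libraries in 4 expression profiles × 3 replicates: profiles draw
log-normal (σ = 1.2) locus weights independently, replicates share the
profile's weights and differ only in sampling seed. Library size in the
shipped study configuration is 50 000 reads — deep enough that planted
loci comfortably clear the ≥ 2-copy and > 5-read thresholds and replicate
profiles cluster cleanly, while keeping a full run to tens of seconds.

What the simulator does **not** emulate: quality-score structure (all 'I'),
indels, PCR duplication and ligation bias, expression correlation between
profiles, cross-species conservation, and genome repeat structure (the
background is uniform random, so multimapping is essentially absent).
Passing tests therefore demonstrate correctness of the pipeline's logic
under its stated assumptions, not robustness to real-library artefacts
such as biased ligation or repeat-derived small RNAs.

## Numerical and testing choices

Log-sum-exp accumulation keeps the inside algorithm exact in log space (no
scaling needed at ≤ 200 nt). The fold DP and its traceback are integer
arithmetic on float arrays; determinism everywhere comes from explicit
tie-break rules and seeded generators (`numpy` `SeedSequence` spawning, so
library seeds are decorrelated). Oracle tests compare: the aligner to a
naive scan (500 random cases), the fold DP to exhaustive structure
enumeration (200 sequences ≤ 25 nt), the inside algorithm to forward
derivation enumeration of a small grammar (all derivable strings ≤ 12 nt),
and clustering heights to scipy. Binomial self-checks use central 99 %
intervals; with hundreds of (locus, library) pairs a ~1 % miss rate is
expected and the tests allow it.

## Known limitations

- Exact-match-only alignment means a single sequencing error hides a tag
  (by design, mirroring the stringent original workflow).
- The hairpin gate's subwindow grid assumes precursors ≤ ~67 nt; plant or
  analyse longer hairpins and the grid needs widening.
- The SCFG is intentionally minimal (76 productions); it captures
  stem/bulge/loop statistics but not sequence motifs of processing sites.
- Arm-ratio classes near the 0.75 / 2.2 bin edges are sampling-noise
  sensitive at low counts; the undefined class absorbs zero-star loci.
- Mirtron calling requires exact splice-site anchoring by default; relax
  the tolerance for annotation sets with imprecise intron boundaries.
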