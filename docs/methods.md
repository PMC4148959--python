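# Methods

## Model and rationale

`micseq` targets insertions that are present in a meaningful fraction of a
population but absent from the reference assembly. The observable signature
in paired-end data is the one-end-anchored (OEA) pair: one mate maps
uniquely (the anchor), its mate — drawn partly or wholly from the inserted
sequence — does not (the orphan). Three facts drive the design:

1. **Pooling turns commonness into coverage.** One 4× genome contributes a
   handful of orphans per insertion; pooling N individuals with carrier
   allele frequency f gives ≈ 2·N·f carrier haplotypes at ~2× each, so the
   pooled orphan depth over the insertion interior is ≈ 4·N·f. A mean k-mer
   coverage cutoff of 50× on the assembly therefore *is* the commonness
   filter: with N = 200, insertions clear it when f ≳ 0.15–0.2 (allowing
   for k-mer edge effects of roughly (L_read − k + 1)/L_read and binomial
   noise in the carrier count). This arithmetic, not a separate threshold,
   decides what is discoverable.
2. **Anchors carry the locus.** Orphans sit within one insert size of their
   anchors, so the anchors of a real insertion cluster in a few hundred
   bases, while mis-assemblies recruit reads whose anchors scatter — the
   basis of the 50%-within-4-kb filter and of breakpoint estimation.
3. **Everything downstream is recomputable.** Carrier status is re-derived
   by mapping each sample's orphans back to the final sequence, not by
   tracking which reads the assembler consumed, so frequencies can be
   recomputed post hoc with different thresholds.

## Pipeline stages and key parameters

| parameter | default | meaning |
|---|---|---|
| trim window / min mean Q / min len | 4 nt / 25 / 20 nt | sliding-window truncation; short reads drop the pair |
| min_mapq | 20 | "uniquely mapped" proxy for anchors |
| k grid | 19…59 step 4 | multi-k de Bruijn assembly |
| cov_cutoff / rescue | 50× / 20× | mean k-mer coverage (commonness filter); relaxed pass for multi-candidate regions |
| min contig length | 100 nt | shortest reportable candidate |
| e-value edge | 1e-10 | similarity-graph edge criterion |
| ref identity / coverage | 0.95 / 0.90 | "alignable" in all reference/contaminant screens |
| DUST window / threshold / fail frac | 64 / 2.0 / 0.80 | low-complexity mask |
| cluster window / min fraction | 4000 nt / 0.5 | anchor-cluster filter |
| local-reference pad | 1000 nt | context extracted under the cluster |
| carrier reads / commonness floor | 3 / 1% | per-sample carrier rule; minimum overall carrier fraction |
| evidence flag | >100 reads | expressed/bound call for evidence datasets |

Trimming is 3'-truncation only: the read is scanned 5'→3' and cut at the
first base of the first window whose mean quality falls below threshold;
trailing windows are evaluated on their actual length. Pair classification
is exhaustive and mutually exclusive (concordant / discordant-both-mapped /
OEA / full-orphan); a sole mapped mate below min_mapq is not a trustworthy
anchor and demotes the pair to full-orphan. Full-orphan pairs are counted
and retrievable but not assembled in the main path.

**Assembly.** Canonical (double-stranded) k-mer counting; unitigs are
maximal unbranched paths; dead-end unitigs shorter than 2k with mean
multiplicity below cutoff/4 are clipped; k-mers below the cutoff are
deleted and unitigs recompressed. There is no bubble popping, error
correction or scaffolding — at desk scale the coverage cutoff does the
cleaning, and near-identical contigs from different k are reconciled by the
similarity graph. Traversal seeds are visited in lexicographic order and
final contigs are orientation-voted by the (orientation-normalized) input
reads, so output is invariant to read order. Orphans of forward-strand
anchors are reverse-complemented before assembly, putting all orphans on
the inserted sequence's forward sense.

**Similarity graph.** Contig pairs sharing an exact 15-mer (either strand)
are aligned with affine-gap Smith–Waterman (match +1, mismatch −2, gap open
−5, gap extend −2); an edge requires e-value < 1e-10. The seed prefilter is
lossless for the graph: an alignment clearing 1e-10 at these scores implies
a long exact stretch. The e-value is Karlin–Altschul E = K·m·n·e^(−λS) with
λ solved numerically for the scoring scheme under uniform base composition
and K fixed at 0.3. Computing K exactly (the BLAST lattice series) is not
worth the complexity here: across contig sizes ≤ 2 kb, related pairs score
E < 1e-20 and unrelated pairs E > 1e-4, so any order-one K yields the same
graph; the constant is exposed for audit in `micseq.align.KARLIN_K`.

**Filters** run in a fixed order — known/low-complexity, anchor cluster,
local reference, contaminant — and every applied filter appends exactly one
verdict to the candidate's audit trail. The anchor-cluster window is the
leftmost 4 kb window holding the maximum number of distinct supporting pair
ids (anchors on several chromosomes are judged on the modal chromosome but
still dilute the fraction). Regions where more than one filtered candidate's
clusters overlap are re-assembled at 20×; the longest rescued contig
replaces the group if it is at least as long as the longest member, and the
rescued candidate re-enters the filter chain.

**Breakpoints.** Within the cluster window, forward-strand anchors approach
the insertion from the left (L = max anchor end) and reverse-strand anchors
from the right (R = min anchor start). When both flanks exist and agree
(L ≤ R + 500 nt) the call is the point ⌊(L+R)/2⌋; otherwise the call is the
anchor span — an interval at the ~1 kb resolution the anchors support. The
500 nt tolerance is about 1.7 insert-size standard deviations at the
defaults; with two-sided evidence the point call lands within a few bases
of the true locus on simulated data.

**Carriers and frequencies.** A sample carries a call when ≥ 3 of its
orphan reads map to it (exact 15-mer seed, ungapped extension, ≥ 95%
identity over the overlap); population frequency is the carrier fraction,
and calls below 1% overall carrier fraction are dropped. Reported
frequencies are *carrier* (sample-level) fractions — ≈ 1 − (1 − f)² under
Hardy–Weinberg for allele frequency f — with a modest downward bias because
a heterozygous carrier at 4× occasionally contributes fewer than three
orphans (observed error ≤ 0.15 absolute on simulated cohorts).

**Stratification.** Printed per-population frequencies are converted to
allele counts by round-half-up of freq × n × ploidy (ploidy 2 by default,
exposed because published tables do not always say whether frequencies are
allele- or carrier-level), and each row is tested African vs pooled
non-African with a two-sided Fisher's exact test. The test choice is an
assumption — it reproduces the packaged validation panel's published
summary (12/15 African-maximum, 9/15 significant at 5%, micSeq30 at
p ≈ 1.2e-7) — and no multiple-testing correction is applied since the
summary is reported at the raw 5% level.

## The simulator, and what passing tests do not show

`micseq.simulate` draws a uniform-random reference, complexity-normal
insertion sequences guaranteed novel against it, binomial genotypes at the
target allele frequency (optionally population-private), fragments with
insert size ~ Normal(300, 30) truncated at twice the read length, FR mates
of 100 nt, i.i.d. substitution errors at 0.002 (constant Q27 qualities, the
Phred equivalent of that rate), and *ideal* alignments: a read maps iff
≥ 95% of its bases are reference-derived, at its reference projection.
Everything is reproducible bit-for-bit from (config, seed); each individual
uses `default_rng((seed, index))`.

The ideal aligner is a deliberate choice: it isolates the pipeline's own
computation from aligner behavior, making recovery tests exact. It also
means passing tests say nothing about mapping artifacts real aligners
produce — multi-mapping in repeats, soft-clip handling, MAPQ miscalibration
— nor about indel sequencing errors, GC bias, duplicates or adapter
contamination, none of which the simulator models. The random reference has
no repeat structure, so the known-sequence and low-complexity screens are
exercised only by planted positives.

## Problem sizes and the insertion-length limit

Default test/acceptance cohorts use 200 diploid individuals at 4× over a
100 kb reference with insertions of 150–300 nt at allele frequencies
0.30–0.35 — sizes chosen so the pooled-coverage arithmetic above predicts
the 50× cutoff is cleared with margin, while a full ten-seed recovery study
runs in minutes on one core. Recall on that design is 1.0 across ten seeds,
with every breakpoint within one insert size of truth, and twenty
zero-insertion cohorts produce zero calls.

Orphans of OEA pairs reach at most ≈ insert_mean + 4·sd − read_len − 95
≈ 320 nt into an insertion (the anchor must keep ≥ 95 reference bases), so
insertions longer than ≈ 450 nt have an interior no OEA orphan can sample:
pairs wholly inside are full orphans, which the main path does not
assemble. Such insertions are recovered as correct but partial
edge-anchored calls (a dedicated test documents this), and insertions
around 400 nt assemble as two fragments that the 20× rescue usually — not
always — stitches. Assembling full-orphan reads to extend long insertions
is the natural extension and is out of scope here.

## Numerical and degenerate-input choices

Ties everywhere break deterministically: lexicographically smallest k-mer
seeds traversal, longest-then-highest-coverage-then-smallest-sequence picks
representatives, leftmost window wins cluster ties. Empty reads trim to
dropped; empty read sets assemble to nothing; a candidate with anchors on
several chromosomes is clustered on the modal one; local-reference padding
clips at chromosome edges; Fisher's test returns p = 1 on degenerate
margins. Odd k only, so no k-mer is its own reverse complement. The
`both` assembly mode unions joint and per-population calls, collapsing
sequences that align at ≥ 95% identity over ≥ 90% of the shorter and
keeping the longer.
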