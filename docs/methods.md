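# Methods

## Overview

`bcrasm` reconstructs the two immunoglobulin chain transcripts of a single
B cell from its short RNA-seq reads by anchoring on known germline variable
and constant regions and then extending those anchors de novo through exact
suffix–prefix read overlaps. The method assumes substitution-dominated
divergence (somatic hypermutation and sequencing error are point events),
orientation-agnostic reads, and roughly uniform coverage of the chain
transcripts; it makes no use of read pairing or base qualities.

## Stage 1: anchoring

The four germline components (IGHV, IGHC, pooled IGK/LV, pooled IGK/LC)
are indexed by exact k-mers (default **k = 16 bp**). Each read is placed on
each component in both orientations by k-mer seeding: every read k-mer
votes for a (germline, diagonal) candidate, and each candidate is verified
by Hamming comparison over the read/germline intersection, which must span
at least k bases (reads may overhang germline ends, so offsets can be
negative). Placements with more than **max_mismatches = 3** substitutions
(per 50 bp read; tolerates ~3% SHM plus sequencing error) are discarded.
Per (germline, orientation) only the best diagonal is kept; a read may
still place on several germlines, which is what makes the pooled
kappa/lambda components a genuine competition.

For each component, every window of **w = 50 bp** (one read length) on
every germline is scored by the number of placements intersecting it by at
least 1 bp; the argmax is the anchor. Ties break by germline name, then
window start, so anchoring is deterministic. A window needs
**min_anchor_support = 3** reads; components below that yield no anchor,
and a cell with no anchor in any component raises a distinct
"no immunoglobulin signal" error (CLI exit code 3). Indexing and mapping
are internal and exact-seeded rather than delegated to an external aligner,
so the pipeline is self-contained and bit-reproducible; the anchor finder
is written against the index interface, so a wrapper around an external
mapper could be substituted.

## Stage 2: greedy anchor extension

Reads of length ≥ m contribute their forward and reverse-complement
**m = 20 bp** prefixes to a prefix map (m is chosen below half a read so
two 50 bp reads can chain, but long enough that random 20-mer collisions
are negligible; values below 10 bp are refused). To extend a contig 3', the
candidate overlap lengths L from min(contig, longest read) down to m are
probed: an overlap of L places a read's m-prefix at contig position
len − L, so that m-mer is looked up and surviving candidates are verified
over the full overlap. Overlaps are **exact by default**
(`overlap_mismatches = 0`): greedy extension with inexact overlaps
compounds errors, and germline divergence is already absorbed by the
anchors. Each candidate read therefore carries its maximal exact overlap;
the winner has the longest overlap, with ties broken by shortest appended
suffix, then lexicographic oriented sequence, then read id — extension is
fully deterministic. Extension stops when:

* no read overlaps the contig end by ≥ m (`no_overlap`);
* the best candidate was already incorporated in this extension pass
  (`repeat` — the concrete reading of "a repeat is found"; each read is
  used at most once per anchor);
* the contig exceeds **max_contig_length = 1500 bp** (~a full-length chain
  transcript), guarding runaway extension through repetitive constant
  regions.

5' extension is the mirror image, implemented as reverse-complement →
3'-extend → reverse-complement; the recorded steps are flipped back to the
contig frame, and the identity `extend_5prime = rc ∘ extend_3prime ∘ rc` is
asserted as a metamorphic test. The V- and C-anchored extensions of one
chain run with independent `used` sets, since the reporting rule treats
them as two potentially complete sequences.

**Merging.** The two extensions rarely have byte-identical extents, so
"equal" is operationalized as: one sequence contains the other, or they
share an exact suffix–prefix overlap ≥ m (the union is reported). Otherwise
the chain is reported `split` with both contigs; a single anchor gives
`partial`, none gives `absent`. The rule applied is recorded in the run log.

## Annotation

Contigs are annotated by best-hit local alignment (match +1, mismatch −1,
gap −2; biopython's PairwiseAligner) against each germline segment set:
V and C always, J when a J set is supplied. A call requires an alignment
score ≥ **min_call_score = 30**; ties break lexicographically. Calls are
gene-level by default (allele suffix stripped), with an allele-level
switch. D segments are not called: at ~15 bp they are too short for a
reliable best hit at this granularity. Merged assemblies are annotated on
the merged sequence; split assemblies get V (and J) on the
variable-anchored contig and C on the constant-anchored one.

## The simulator

The generator produces what the assembler must survive, with ground truth:

* **Recombination**: V, (D), J and constant genes drawn uniformly; light
  chains pick a kappa/lambda locus first so V/J/C are locus-consistent
  (the assembler still sees only the pooled components).
* **Junctional diversity**: 0–3 bp trimmed at each joint (`max_trim = 3`),
  plus a non-templated insertion of 0–8 bp (`insertion_range`) at each
  junction — heavy V–D and D–J, light V–J.
* **SHM**: i.i.d. substitutions over the V(D)J span at `shm_rate`;
  substitution-only, so the exact-overlap recovery property stays well
  defined (an indel-free model is a stated limitation, not an oversight).
* **Reads**: fixed-length (default 50 bp) reads at
  `round(depth × len / read_length)` per transcript, strand uniform,
  i.i.d. substitution errors at `error_rate`. Read starts are uniform
  *with overhang past both transcript ends*, then clipped to the
  transcript; clipped reads shorter than 20 bp are redrawn. This emulates
  tagmentation of full-length amplified cDNA, where fragments include the
  transcript termini; a no-overhang uniform model leaves a transcript's
  terminal bases uncovered with appreciable probability even at 100×,
  which real libraries do not show. Paired mode draws fragments with
  normal length (mean 300 bp, sd 30 bp) and emits mates from opposite
  ends. An optional `mask_interval` discards reads overlapping a
  transcript interval to create controlled coverage gaps.

The shipped germline set is synthetic — random sequences with IMGT-like
names (~300 bp V, 15 bp D, ~40–52 bp J, ~300 bp constant-region 5'
truncations), deterministic for a given seed, and explicitly not real
human alleles. What passing tests on it demonstrate is the correctness of
the anchoring/extension/merging/annotation machinery under the modeled
noise; they do not demonstrate robustness to features the generator omits:
real allele similarity within gene families (toy genes are mutually
random, so best-hit calling is easier than on IMGT data), 3' coverage
bias, intronic/partially spliced reads, contaminating transcripts, indel
errors, and clonally related cells.

## Problem sizes and numerical choices

The packaged validation regimes use 50 simulated cells per condition at
100× depth with 50 bp reads: zero-noise cells must merge, contain the full
truth transcript and annotate perfectly; cells at 3% SHM + 0.5% error must
reach ≥ 90% correct V-gene identification. Under noise the exact-overlap
rule often stalls extension before full length (an appended erroneous base
poisons the contig terminus), so merged status is *not* required there —
V-gene identification is the accuracy criterion, and in practice it stays
at 100% on the toy set. Simulator calibration checks compare realized SHM
and error counts per seed against closed-form binomial 99% intervals over
100 seeds, requiring ≥ 95% coverage (the nominal per-seed violation rate
is 1%). All randomness flows through seeded numpy generators; assembly
itself is seed-free, and reruns are byte-identical.

## Known limitations

* Substitution-only placement and exact-overlap extension: indels in reads
  or true indel SHM break extension at that point (the chain then reports
  `split`/`partial` rather than a wrong sequence).
* No consensus polishing: a sequencing error incorporated into an appended
  suffix remains in the contig.
* No CDR3/junction delineation, clonotype grouping, isoform awareness, or
  expression quantification.
* Anchor choice takes the single best window per component; a cell with
  two expressed alleles (or a doublet) yields one chain per locus at most.
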