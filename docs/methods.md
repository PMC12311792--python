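# Methods

This note documents the models behind `dpcseq`: what the synthetic-data
generator emulates, the statistics the pipeline computes, the defaults and
why they were chosen, and what the package's passing tests do and do not
say about real sequencing data.

## The simulated study

The generator (`dpcseq.simulate`) emulates a formaldehyde DPC-seq
experiment in a human fibrosarcoma-like cell system: three treatment
conditions — untreated control (C), harvest immediately after a 2-h
formaldehyde exposure (T), and harvest after a 5-h drug-free recovery (R) —
across four genotypes: wild type (WT), XPA knockout (core nucleotide
excision repair scaffold, both sub-pathways), XPC knockout (global-genome
NER sensor only), and CSB knockout (transcription-coupled NER initiator).

### Toy genome

`build_toy_genome` lays out `n_chromosomes` chromosomes totalling
`genome_length` bases (default 2 × 1 Mb — small enough that every analysis
runs in seconds on one core, large enough for ~165 genes and ~240
chromatin-state blocks, which keeps each expression stratum above 25
genes). Each chromosome is partitioned exactly into state blocks of
uniform-random length (2–15 kb) labeled with the 18 ChromHMM-style states;
states are assigned by cycling through shuffled permutations so all 18
labels always occur. Genes are placed non-overlapping with random strand,
lengths 3–12 kb and gaps 1–8 kb; FPKM values are a mixture of 30% exact
zeros (the Q0 pool), 5% sub-threshold values in (0, 0.1), and log-uniform
expression over 0.1–500 FPKM.

### Formation model

C-condition fragments are uniform over the genome at `baseline_intensity`
(0.5 fragments/kb): steady-state DPCs are modeled as evenly distributed.
T-condition fragments are Poisson per state block with per-state
intensities (`state_formation_intensity`, fragments/kb). The default vector
puts the highest rates on Polycomb-repressed and bivalent states (ReprPC 8,
TssBiv 7, EnhBiv 6.5), elevated rates on strong transcription, weak
enhancers and ZNF/repeats, and the lowest on quiescent and heterochromatic
states (1.2–1.5) — the qualitative pattern formaldehyde produces, with a
base-weighted mean of ~4.2 fragments/kb so the T/C induction ratio is ~8,
comfortably above the greater-than-six-fold induction the formation
analysis is calibrated to. Fragment lengths are uniform over 200–500 bp,
the sonication window of the assay.

### Removal model

R-condition libraries are an independent T-law draw thinned fragment by
fragment. A fragment overlapping a gene in expression stratum q of genotype
g survives with probability `1 − quintile_removal[g][q]`. Defaults set the
removal fraction at the most-transcribed stratum (Q4) to WT 0.72, XPA-KO
0.40, XPC-KO 0.72, CSB-KO 0.10, with a transcription-independent baseline
of 0.10 at Q0 and linear interpolation across Q1–Q3. The 0.72/0.40 pair is
the package's calibration of efficient vs NER-impaired removal at a
transcribed locus; XPC-KO matching WT encodes that global-genome-only loss
leaves transcription-coupled removal intact, and CSB-KO at baseline encodes
loss of the transcription-coupled branch itself. Intergenic fragments are
thinned at the genotype's Q0 baseline: a zero intergenic rate would make
silent gene bodies appear preferentially repaired relative to their own
flanks, which contradicts the uniform non-transcribed behaviour the model
is meant to express.

Thinning is uniform over the gene body by default, which makes the survival
probability of a stratum-q-overlapping fragment exactly `1 − removal[g][q]`
— the property the binomial-oracle tests pin down. An optional
`tss_decay_bp` knob instead scales the thinning probability by a weight
falling linearly from 1 at the TSS to 0 at that distance downstream,
producing profiles that decay with the direction of transcription; it is
off by default because it changes the per-gene aggregate removal and thus
breaks the simple survival contract.

### Repeat locus and qPCR

The repeat reference holds one canonical repeat sequence (default 13,357 b,
the length of the human 45S pre-rRNA unit this emulates) plus panels of
non-transcribed (Q0) and highly transcribed (Q4) control genes (default
100 per panel, 2 kb each; tests shrink the panels for speed). Reads
(default 150 b) start uniformly within a target, come from either strand,
and carry uniform substitution errors (default 0.001/base). Per-target
expected depth is `repeat_read_depth` for T and is scaled by
`1 − repeat_removal[group]` for R; the default removal vector (repeat 0.10,
Q0 controls 0.10, Q4 controls 0.72) expresses a repeat locus that escapes
transcription-coupled removal despite being transcribed — its polymerase
does not recruit that pathway.

The qPCR forward model draws `Ct_T` around a base cycle (22) and
`Ct_R = Ct_T − log₂(1 − f) + ε`, ε ~ N(0, `ct_noise_sd`), for true removal
fraction f, so the downstream transform `(1 − 0.5^ΔCt) × 100` recovers
100 f on average (the exponential transform adds a relative bias of order
`(σ ln2)²/2 ≈ 0.5%` at σ = 0.15, far below replicate noise).

### Seeding

All randomness flows from one master seed. Independent streams are derived
per purpose and per (condition, genotype, replicate) by hashing string tags
with CRC32 into numpy `SeedSequence` spawn keys (`simulate.substream`), so
outputs are byte-reproducible and never depend on call order.

## Analysis statistics

**Peak calling** is a deliberate stand-in, not a MACS2 reimplementation:
bins of the CPM track at or above `min_fold` (default 2) times the control
track — or the genome-wide mean when no control exists — are flagged,
flagged runs closer than `merge_gap` (1 kb) merge, and merged runs shorter
than `min_width` (200 b) drop. The scientific quantity is the downstream
fold-enrichment statistic, which is computed on merged peaks in base units
so double-covered bases count once; states never placed in the segmentation
are reported missing, not zero. A state-base-weighted mean enrichment of
exactly 1 over a genome-covering segmentation is an identity the tests
verify.

**CPM tracks** use 10-b bins; every bin a fragment overlaps is incremented
(full-insert coverage) and values scale by 10⁶/total fragments. Note the
consequence for T→R comparisons: CPM is depth-invariant, so removal at
transcribed loci re-appears as a pro-rata gain at untouched loci. Stratum
"percent signal loss" numbers are therefore relative redistributions; their
ordering across strata and genotypes, not their absolute values, carries
the biology.

**Strata** keep the field's "quintile" naming although Q1–Q4 are rank
quartiles of expressed genes (FPKM ≥ 0.1, ascending, ties broken by gene id
for determinism, sizes differing by at most one) and Q0 is a seeded sample
of FPKM = 0 genes. Genes with 0 < FPKM < 0.1 belong to no stratum and are
reported, never silently dropped. Stratum sizes are configuration, not
constants.

**TSS matrices** span ±`window` (default 20 kb) around each TSS in 10-b
bins, rows of minus-strand genes reversed so columns run in transcription
direction; rows crossing a chromosome edge are zero-padded and flagged.
Position-wise genotype comparisons take replicate-level stratum means per
column and apply the paired one-tailed t-test; directions are always
explicit arguments, never inferred.

**Repeat counting** matches 50-b hard-trimmed reads as exact substrings of
a target or its reverse complement (libraries are unstranded; the reverse
strand is switchable). This equals zero-mismatch alignment for reads
without indels; indel-bearing reads simply fail. Reads matching targets in
more than one group are discarded as ambiguous, in the spirit of
unique-mapping filters; matched + ambiguous + unmatched always equals the
read total. RRE uses raw counts — no depth normalization between T and R
libraries by default, matching how equal-input libraries are compared; the
drivers and `compute_rre` work from per-replicate counts so a caller can
rescale first if depths diverge.

**Tests and error bars.** The paired one-tailed t-test uses
`t = mean(d)/(sd(d)/√n)` with the n−1 denominator and Student's t on n−1
degrees of freedom (tail probabilities from scipy). Zero-variance
differences are degenerate: p = 1 when the mean difference is also zero, a
flagged 0/1 limit otherwise — needed for identical-input edge cases, which
real data never produce. SEM is sd(n−1)/√n and is undefined (not zero) at
n = 1. Percent removal is transformed per replicate and then averaged,
consistent with the per-experiment discard of negative-ΔCt replicates;
discard counts are always reported.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; strand lives on genes,
  intervals are unstranded.
- Readers reject malformed input with the line number; they never repair.
- Fold enrichment with an empty peak list, a zero-base state, or a
  zero-variance correlation vector is missing (NaN), never zero.
- RRE with a zero R count raises, naming the replicate.
- Fragments are kept fully inside their chromosome by shifting starts near
  the edge, preserving the configured length range exactly.

## What passing tests do and do not show

The generator reproduces the mechanisms the pipeline measures — state-
dependent formation, transcription-graded genotype-dependent removal,
repeat-locus escape, Ct shifts — under idealized conditions: Poisson
fragment counts, uniform substitution errors only (no indels, no quality
gradients, no PCR duplicates, no adapter read-through), a haploid toy
genome with non-overlapping genes, and no mappability or copy-number
structure. Passing tests validate the statistics and their implementation,
not the wet-lab assay; absolute simulated scales (fragments per Mb, read
depths) are arbitrary choices documented above, since the assay itself
reports only relative quantities.

A property of the assay worth knowing: the per-replicate spread of the
percent-removal estimate scales as `100·ln2·(1−f)·σ_Ct`, so the estimate is
precise where removal is high (~2 points sd at f = 0.72, σ = 0.15) and
noisy where removal is low (~10 points at f = 0); and discarding
negative-ΔCt replicates biases the retained mean upward when true removal
is near zero. The test suite asserts the tight recovery claim only where
the arithmetic permits it and pins down the low-removal variance and bias
explicitly.

## Problem sizes

Default simulations (2 Mb genome, ~8,500 T-fragments per replicate, repeat
panels of 100 × 2 kb at depth 200 reads/target, 3 replicates) complete the
full `run-all` in well under a minute on one core; the test suite uses
further-reduced configurations (0.4–1.2 Mb genomes, panels of 3–5 controls)
chosen as the smallest sizes at which each statistical assertion retains
power.
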