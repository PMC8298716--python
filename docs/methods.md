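# Methods

## Scope and model

`pirnakit` quantifies annotated piRNAs from single-end small RNA-seq
libraries and characterises the consistently expressed set of a focus
tissue. The unit of analysis is the annotated piRNA — a mature sequence of
23–40 nt plus the set of genomic loci it maps to — not the locus: a read is
evidence for a piRNA species, and a piRNA transcribed from 150 loci still
receives one count per read. Locus information enters only in the
multiplicity and region-membership reports.

### Read quality control

Reads are processed in a fixed order; the categories partition the input
and each read is counted under exactly one removal reason:

1. **Adapter trimming.** The 3′-most position at which a prefix of the
   configured adapter (≥ 5 nt, exact match) runs through to the end of the
   read (or a full internal adapter occurrence) is cut, together with
   everything after it. Reads left empty are tallied as `adapter_only`.
2. **Length window / quality floor**, reasons assigned in the order
   `too_short` (< 16 nt), `too_long` (> 40 nt), `low_quality` (summary
   Phred < 20). The quality summary is the *mean* per-base Phred by
   default; a `min` mode is available (`FilterConfig.phred_summary`). All
   boundaries are inclusive on the retain side: lengths 16 and 40 and a
   mean Phred of exactly 20 are retained.
3. **miRNA-length exclusion** (`mirna_length`): reads shorter than 23 nt
   are dominated by miRNAs and are excluded from piRNA assignment; the
   strict "< 23" boundary retains 23-nt reads. This runs before
   assignment.

The adapter sequence is a required input (it is platform-specific); the
simulator documents its own (`AGATCGGAAG`, the common Illumina 3′ adapter
prefix).

### Assignment

Read-to-piRNA assignment is by exact sequence identity against the
annotation: a read supports a piRNA when it equals the annotated mature
sequence or is a contiguous subsequence of it of length ≥ 23 nt. This
replaces genome alignment plus coordinate overlap: mature piRNA annotations
are defined by their sequences, so exact matching is deterministic,
oracle-checkable (the test suite compares it against a brute-force
all-pairs substring scan), and needs no aligner. Reads matching several
distinct piRNA sequences increment each matching piRNA by one (fractional
splitting is deliberately not the default; per-piRNA expression remains
interpretable and the behaviour is easy to reason about in tests). The
implementation precomputes a substring→piRNA index so each read costs one
dictionary lookup. Coordinate-based counting from externally produced
alignments can be plugged in by supplying a counts matrix directly to the
downstream stages, which only consume `CountsMatrix`/`ExpressionMatrix`.

### Normalisation and the consistency filter

Counts are scaled to reads per million (RPM) of the sample's library size,
defined as the QC-retained piRNA-candidate read total (after all four QC
stages). The true "mapped reads" denominator of an aligner-based pipeline
is not reproducible without the aligner; the retained-candidate total is
deterministic, and since it is shared by all piRNAs of a sample it leaves
within-sample ratios untouched. RPM (not RPKM) is used throughout; piRNAs
are near-constant in length, so a per-kilobase correction would only add a
sequence-length covariate to a 23–32 nt range.

A piRNA is *consistently expressed* iff

* its summed count across the discovery cohort is ≥ `min_total_reads`
  (default 10), and
* its RPM is ≥ `min_rpm` (default 1.0) in at least
  max(1, ⌈`min_sample_frac` · n⌉) of the n cohort samples (default 10 %).

Both boundaries are inclusive. The cohort is the focus tissue's samples;
per-tissue detection in the comparison stage applies the same two criteria
within each tissue's samples, so a 3-sample tissue requires ≥ 10 reads and
one sample at ≥ 1 RPM. "Detected" (as opposed to consistently expressed)
is defined as ≥ 1 assigned read in ≥ 1 sample and is labelled as such in
reports.

### Multiplicity and membership

Locus multiplicity is the number of distinct annotated intervals
(duplicates de-duplicate); bins default to 1 | 2–9 | 10–100 | > 100 with
configurable edges. Distinct-locus totals de-duplicate identical intervals
*across* piRNAs: "n loci" counts genomic locations, not (piRNA, locus)
pairs. The low-multiplicity locus total counts the distinct loci of piRNAs
below the "mid" bin edge (< 10 loci by default). Region membership is
piRNA-level: a flag is true iff ≥ 1 locus overlaps the region set by ≥ 1 bp
under half-open coordinates; strand is stored but ignored (a strict mode
flag is reserved). Mitochondrial membership means any locus on `chrM`.
Percentages against a known reference total (e.g. expressed mitochondrial
piRNAs as a share of all annotated chrM piRNAs) are rounded to the nearest
integer.

### Tissue comparison

* **Exclusivity**: a kept piRNA is `exclusive_to_focus` when detected in
  the focus tissue and nowhere else, `ubiquitous` when detected in every
  tissue, otherwise `other`.
* **Fold bias**: the ratio of focus to reference median RPM (pseudocount 0
  by default; configurable). A reference tissue with zero counts
  everywhere is routed to `not_detected_in_reference` before any division.
  Ratios at or above `fold_threshold` (default 5) in either direction give
  `focus_biased` / `reference_biased`; the calls are antisymmetric under
  swapping focus and reference for piRNAs expressed in both.
* **Clustering**: piRNA rows are transformed log₂(RPM+1) (variance
  stabilisation; raw mode available) and clustered with average linkage on
  Euclidean distances (both configurable). The dendrogram is materialised
  with per-node member lists and exported as Newick.
* **Node extraction** operationalises "highly and nearly exclusively
  expressed in the focus tissue": a leaf qualifies when its pooled
  focus-vs-rest median-RPM ratio, stabilised with a 10-RPM pseudocount,
  reaches the factor (default 100); the extracted node is the smallest one
  containing every qualifying leaf whose pooled member values also reach
  the factor. The pseudocount keeps low-expression piRNAs with empty
  non-focus medians from producing unbounded ratios, and the two-order-of-
  magnitude factor separates "high and nearly exclusive" from merely
  focus-biased (≈ 5–15×) or low-level exclusive piRNAs. With no qualifying
  leaf the result is empty, not an error. The extracted node is profiled
  against a named region: (members, single-locus members, members with a
  locus in the region).
* **t-SNE**: samples are embedded in 3-D (perplexity 10, 1,000 iterations,
  PCA initialisation, fixed seed recorded in the result) on the same
  log-transformed values; the embedding requires n_samples > 3·perplexity.
  Focus-group separation is summarised as the mean silhouette of focus
  samples under a focus-vs-rest labelling.

## The simulator

`simulate_study` plants a complete study whose defaults are the conditions
every acceptance check runs under:

* **Genome**: 24 nuclear chromosomes of 2 Mb, `chrM` of 16,569 bp, twenty
  60-kb cluster regions, one 40-kb imprinted interval ("MEG8") on chr14.
  Compact chromosomes keep interval arithmetic realistic (clusters,
  imprinted region and loci all fit with room for rejection sampling)
  without carrying hg19-scale coordinates.
* **Annotation**: 297 expressed piRNAs with multiplicity mix 151 single /
  116 at 2–9 loci / 0 at 10–100 / 30 at > 100; the 2–9 bin carries 485
  loci (95×4 + 21×5) so the < 10-loci subset spans exactly 636 distinct
  locations. 15 singles sit inside the imprinted region, 19 singles on
  chrM; no expressed piRNA touches a cluster. 80 background piRNAs are
  added (23 more on chrM — 42 annotated mitochondrial piRNAs in total —
  and 10 inside clusters). Sequences are 23–32 nt, unique, mutually
  non-substring, and free of the adapter seed, so exact-match assignment
  is one-to-one and planted counts are recovered exactly.
* **Expression classes** within the 297: a 16-member node (the 15
  imprinted singles plus one multi-locus piRNA; mean 800 in placenta, 15
  in adrenal/brain, 0 elsewhere), 11 exclusive (mean 20, placenta only),
  53 ubiquitous (150 everywhere; includes the 19 mitochondrial), 22
  focus-biased (500 vs 50 in testis), 95 reference-biased (30 vs 400), and
  100 broad-but-uneven piRNAs. Background piRNAs get mean 6 in two random
  samples each — detectable, but incapable of reaching ≥ 1 RPM in three
  cohort samples, so the consistency filter must reject all of them.
  Per-sample means are rescaled so each library's expected piRNA yield is
  depth × piRNA fraction; this mimics the compositional nature of RPM
  (tissues with smaller repertoires amplify the rest).
* **Reads**: per-(piRNA, sample) counts are Poisson around the planted
  means (no model is claimed beyond minimal count noise; an `exact` mode
  rounds the means deterministically). piRNA reads are exact sequence
  copies; 10 % carry the 3′ adapter (recovered by trimming), and a 1-nt
  end-trim rate exists but defaults to 0 so that assignment equals the
  drawn counts exactly. Contaminants per library: 15 % miRNA-length reads
  (16–22 nt), 5 % low-quality reads (mean Phred 5–15), 3 % adapter dimers
  (the bare adapter; trims to empty), 7 % random ≥ 23 nt fragments that
  match no annotated sequence. These fractions are a realistic small-RNA
  library composition chosen once for the default conditions; each class
  maps deterministically onto exactly one QC category, so the QC report
  recovers the planted composition exactly. Depth defaults to 2×10⁵ reads
  per sample across 48 samples (30 placenta / 3 testis / 5 tissues × 3).
* **Determinism**: all randomness flows from one seed through a
  `SeedSequence`; each sample has its own child stream, so FASTQ output is
  byte-identical across runs and independent of consumption order.

### What the simulator does and does not emulate

It emulates the features the pipeline's contracts depend on: multiplicity
structure, region placement, planted tissue specificity, count noise, and
the four QC-relevant artifact classes. It does **not** emulate sequencing
errors, RNA degradation ladders, isomiR-style length heterogeneity beyond
the optional 1-nt trim, genome-alignment ambiguity, batch effects, or real
hg19 sequence content. Consequently, passing recovery tests demonstrates
that the pipeline's logic is correct under its stated matching rule — not
that exact matching is robust to error-rich real reads, where an
aligner-based assignment may differ.

## Problem sizes and numerical choices

The default study (48 samples × 2×10⁵ reads ≈ 9.6 M reads) runs the full
pipeline in about a minute on one core; the test suite's generator tests
use a down-scaled design (19 samples, 2×10⁴ reads) for speed. Ties in node
extraction break toward fewer members, then smaller node id. Degenerate
inputs are errors where the contract says so (empty annotation, zero
library size naming the sample, tissue with no samples, perplexity bound),
and no-ops where not (no adapter match; no node satisfying the predicate).
Matrix round-trips write floats at 10 significant digits (≤ 1e-9 relative
error on re-read).

## Known limitations

* Exact-match assignment ignores sequencing errors and non-templated
  additions; counts on real data will be conservative relative to
  mismatch-tolerant alignment.
* The RPM denominator (QC-retained candidates) differs from an aligner's
  "mapped reads"; absolute RPM values are comparable within a pirnakit
  analysis, not across pipelines.
* Multi-mapping reads are counted once per matching piRNA, so column sums
  can exceed the number of assigned reads when annotation sequences
  overlap; the optional fractional mode is not implemented.
* The node-extraction predicate is this package's operationalisation of a
  visual judgement; the factor/pseudocount defaults suit expression
  contrasts of two orders of magnitude and should be revisited for subtler
  structure.
* Strand-aware overlap is reserved but not implemented; membership is
  strand-blind.
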