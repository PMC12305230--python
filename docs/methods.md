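# Methods

## The estimator

For a gene whose transcript pool is a molar mixture of unspliced pre-mRNA
(fraction φ) and spliced mRNA, and a fragmentation-based sequencing
protocol (fragments per molecule proportional to molecule length), the
expected fragment density per base is

- over introns: proportional to the molar abundance of pre-mRNA,
- over exons: proportional to the molar abundance of pre-mRNA + mRNA.

Length-normalizing intronic and exonic counts per gene and taking their
ratio,

    InEx = TPM_intron / TPM_exon  →  φ · m / (φ · m + (1 − φ) · m) = φ,

where m is the gene's molar abundance. InEx is therefore an estimator of
the unspliced proportion — *comparatively*, not absolutely: coverage
inhomogeneity, boundary fragments and annotation inaccuracies bias it, but
these biases act on PD and Input alike, so the PD-vs-Input comparison of
enriched genes remains interpretable. InEx can exceed 1 (uneven coverage,
annotation errors, or genuinely pulled-down spliced-out introns); values
are reported unclipped with an `above_one` flag.

## Counting semantics and the library size

A fragment is the union of the aligned blocks of a read pair; junction
gaps (CIGAR N), deletions and the unspanned insert between mates are not
aligned bases. Intronic counts use union-mode overlap with intron features
(capturing intron-interior and exon–intron boundary fragments), exonic
counts union-mode overlap with exon features, strictly exonic counts
intersection-strict (every aligned base exonic; junction-spanning
fragments qualify). Multi-feature fragments count once per feature
(nonunique-all), which matters both for per-exon counting (transcripts
share exons) and for fragments spanning two genes.

The per-sample library size is intronic (union) + strictly exonic counts.
Intronic and exonic union counts both contain boundary fragments; their
sum would double-count them, whereas intron-union and exon-strict are
provably disjoint per gene on an unambiguous annotation (a fragment
overlapping an intron has a non-exonic aligned base). CPM against this
library size makes intron and strict-exon CPM sum to exactly 10⁶ per
sample — asserted as a test invariant.

Chimeric (inter-chromosomal) pairs are skipped with a warning; secondary,
supplementary and unmapped records are ignored; a lone mate counts as a
singleton fragment. These conventions assume deduplicated, primary-only
input, the normal state of pull-down libraries after upstream processing.

## Reference construction

Ambiguity removal is strand-aware throughout (reverse-stranded libraries
are the default; forward and unstranded are supported and a diagnostic
recommends the right mode by comparing assignment rates under both).
Subtraction removes every base annotated as exon in one retained variant
and intron in another, regardless of gene; merging coalesces overlapping
*or touching* same-type intervals (the behavior of the standard interval
toolkit) and discards merged features fed by more than one gene. The
builder is tested for exact equality against a brute-force per-base
labeling oracle on random toy genomes, and its subtraction step against
`bedtools subtract -s`.

Transcript-variant filtering retains a variant only if every one of its
exon IDs has a fragment count > 0 in at least one sample (all samples
pooled). Where two variants share an exon ID but differ in coordinates
(an annotation pathology), the ID-based rule conflates them; this is
inherited from the ID-based design and left as a documented limitation.

## Statistics

- Expression cutoff: the unweighted mean of the intron table's per-gene
  mean PD TPM, applied to both categories with a strict `>`. Intronic
  signal is the scarcer category; one shared cutoff keeps the two filtered
  universes comparable.
- Log transform: natural log, no pseudocount; rows with any non-finite
  value are dropped (zero-signal genes are not of interest here).
- Per-gene test: Welch's unequal-variance t-test by default (log-normal
  RNA-seq abundances are approximately normal after the log), two-sided,
  PD vs Input replicates; pooled-variance Student and Mann–Whitney U
  variants are available. Constant-data genes yield p = 1 with a warning
  rather than aborting the run.
- Multiple testing: Benjamini–Hochberg step-up across all genes of a
  table (never per-group), via statsmodels; checked against a
  hand-rolled step-up oracle and for permutation invariance.
  With 3 vs 3 replicates the Welch test runs slightly conservative
  (measured raw null rate ≈ 0.036 at nominal 0.05); the BH-enriched set
  on null data is empty in practice.
- Enriched: p_adj ≤ 0.05 (inclusive) and logFC > 0 (strict); the target
  set is the union over categories.
- PD-vs-Input InEx comparison: paired t-test on per-gene mean InEx by
  default — the gene sets of the two conditions are identical, so pairing
  per gene is the natural reading; an unpaired Welch variant is available.
  The test uses per-gene means, not pooled replicate values.

## Synthetic data

The generator emulates what the method assumes about real data: genes
with 1–5 isoforms, alternatively spliced cassette exons (exonic in one
variant, intronic in another), isoforms with an extra upstream exon that
are never expressed (so the coverage filter must remove them),
same-strand overlapping gene pairs, single-exon genes, non-coding genes,
and reverse-stranded (configurable) properly paired fragments drawn from
the pre-mRNA/mRNA mixture with molecule pick probability proportional to
molar abundance × molecule length (the fragmentation model that makes
InEx → φ). Simulated RBP targets get an 8-fold molar enrichment in PD and
an unspliced fraction of 0.4 there versus 0.1 in Input.

Defaults: exons 600–1,000 bp, introns 2,500–5,000 bp, 2×60 bp reads with
150 bp inserts, 20–50 genes, 20,000–50,000 fragments per sample, 2–3
replicates per condition. The long-intron geometry is deliberate: InEx
approximates φ only when boundary windows (about a read length around
each exon–intron junction) are small relative to feature lengths; with
read-scale exons the boundary bias dominates and the estimator degrades —
a property of the method, not of the implementation. Measured residual
bias at these defaults is ≲ 0.01 for φ ≤ 0.5 and about −0.05 at φ = 1
(boundary fragments inflate the exonic category most when everything is
pre-mRNA).

What the simulation does *not* model: sequence content and alignment
error (records carry placeholder sequences; the pipeline is
coordinate-based), GC/positional coverage bias, retained introns,
alternative transcription start/termination sites, or UMI/duplication
structure. Passing tests therefore validate the counting, normalization
and inference machinery under the method's own model — not robustness to
those real-data artifacts, whose impact on PD-vs-Input comparisons is
argued (not proven) to cancel between conditions.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; GTF (1-based
  closed) and BED conversions happen only at I/O boundaries.
- Sorting ties (identical starts) break by end, then feature type, for
  determinism.
- Strand "." in input GTFs is rejected at parse time: every downstream
  step is strand-aware.
- A molecule shorter than the configured insert yields a fragment
  covering the whole molecule (deterministic truncation) rather than
  being resampled, which would distort the length-weighted mixture.
- Zero library size, empty annotations, an empty post-cutoff table and a
  vanishing enriched set all produce early, named errors or logged
  warnings; the InEx stage is skipped (with a warning) when no gene is
  enriched.
- All simulation randomness flows through a single integer seed; repeated
  runs are byte-identical, asserted in tests.

## Problem sizes

Validation experiments use 20–50 gene genomes and 20,000–50,000 fragments
per sample, sizes at which the mixture-recovery and calibration
properties are measurable in seconds to a couple of minutes on one core;
the statistical calibration experiments use 500–2,000 genes at the table
level. The pipeline itself streams fragments and scales linearly in
alignments and features.
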