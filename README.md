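# inextools

Does an RNA-binding protein (RBP) bind the unspliced pre-mRNA or the mature
mRNA of its targets? `inextools` answers this from a pull-down (PD) RNA-seq
experiment sequenced alongside a total-lysate Input: it quantifies, per
gene, the ratio of intronic to exonic fragment coverage — the **InEx
ratio** — and compares it between PD and Input. Intronic coverage tracks
pre-mRNA abundance; exonic coverage tracks the whole transcript pool; their
length-normalized ratio estimates the unspliced proportion of a gene's
transcripts. A significantly higher InEx in the pull-down means the RBP
preferentially binds pre-mRNA.

The package is aimed at people analyzing RIP-/pull-down-style RNA-seq
(bulk or single-cell-derived pseudobulk) who have name-sorted, stranded,
paired-end alignments and an Ensembl GTF.

## Method

1. **Unambiguous reference.** Alternative splicing makes "intron" ambiguous:
   the same bases can be exonic in one transcript variant and intronic in
   another. The builder keeps exons of protein-coding variants, drops
   variants with any exon lacking fragment coverage in every sample,
   derives introns as inter-exon gaps per variant, removes (strand-aware)
   every base annotated as both exon and intron, collapses the remainder,
   and discards regions claimed by more than one gene. Every surviving base
   is exonic or intronic for exactly one gene.
2. **Fragment counting.** Per gene and sample, three categories:
   *intronic* = fragments overlapping introns or exon–intron boundaries
   (union mode); *exonic* = fragments overlapping exons, exon–exon
   junctions or boundaries (union); *strictly exonic* = fragments whose
   every aligned base is exonic (intersection-strict). Fragments touching
   several features count for each (nonunique-all).
3. **Normalization.** Library size = intronic + strictly exonic counts
   (each fragment counted once; boundary fragments would be double-counted
   by intronic + exonic). CPM = count / (library size / 10⁶); TPM-like
   value = CPM / feature length in kb, using the per-gene unambiguous
   intron and exon lengths.
4. **Enrichment.** Genes above an expression cutoff (overall mean intron
   PD TPM) are log-transformed and tested per gene, PD vs Input replicates
   (Welch t-test by default; Mann–Whitney available), Benjamini–Hochberg
   corrected across all genes. Enriched: p_adj ≤ 0.05 and
   logFC = mean_PD − mean_Input > 0; the target set is the union over the
   intronic and exonic tables.
5. **InEx.** For enriched genes, per replicate:
   InEx = TPM_intron / TPM_exon; per-gene means are compared PD vs Input
   with a paired t-test (each gene is its own control).

A synthetic-data module simulates genomes with alternative splicing,
unexpressed variants and overlapping genes, and draws stranded paired-end
fragments from a pre-mRNA/mRNA mixture with a known unspliced molar
fraction φ, so the whole pipeline can be validated against ground truth.

## Worked example

Simulate a pull-down experiment for a pre-mRNA-binding protein (target
genes are 8-fold enriched in PD and have unspliced fraction 0.4 there vs
0.1 in Input), then run the full pipeline:

```
$ inex simulate --out-dir demo --n-genes 40 --n-fragments 20000 --seed 7
wrote simulation to demo
$ cat > demo/run.yaml <<EOF
gtf: demo/genome.gtf
design: demo/design.tsv
out_dir: demo/run
strandedness: reverse
alpha: 0.05
EOF
$ inex run --config demo/run.yaml
run complete: demo/run
```

`demo/run/` now contains `annotations.gtf`, `lengths.csv`, TPM tables,
per-category enrichment tables, `inex.tsv` and `comparison.json`:

```
{
  "statistic": 68.13242647304645,
  "p_value": 8.451533528854763e-16,
  "direction": 1,
  "n_genes": 12,
  "test": "paired-t"
}
```

and `inex_summary.tsv`:

```
        n   mean     q1  median     q3    min    max
Input  12  0.102  0.098   0.100  0.104  0.094  0.120
PD     12  0.402  0.394   0.402  0.407  0.381  0.429
```

Twelve pull-down-enriched genes were found; their mean InEx is ≈ 0.10 in
Input and ≈ 0.40 in PD — matching the simulated unspliced fractions — and
the paired comparison is significant with direction +1 (PD > Input): the
simulated protein binds pre-mRNA, which is exactly what was simulated.

Each stage is also available separately (`inex build-annotation`,
`inex count`, `inex quantify`, `inex enrich`, `inex ratio`,
`inex check-strandedness`) and as library functions.

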