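"""Synthetic genomes and stranded paired-end fragments with known truth.

The generator emulates the data model the InEx method assumes: each gene's
transcript pool is a molar mixture of unspliced pre-mRNA (molar fraction
phi) and spliced mRNA, and sequencing fragments a molecule with probability
proportional to its length (the standard fragmentation model — a molecule
twice as long yields twice the fragments).  Under that model the fragment
density per base over introns equals the pre-mRNA molar abundance and over
exons the total molar abundance, so the length-normalized intron/exon ratio
of a deeply sequenced gene converges to phi.

Genomes include the annotation pathologies the reference builder must
handle: multi-isoform genes with alternatively spliced exons (exonic in one
variant, intronic in another), isoforms with an extra uncovered exon that
are never expressed, same-strand overlapping gene pairs, single-exon genes
and non-coding genes.  Sequences are not simulated — the pipeline consumes
only coordinates, CIGAR, flags and names — so SAM records carry placeholder
sequence and quality strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .gtf_io import GenomicInterval, GtfRecord

__all__ = [
    "IsoformTruth",
    "GeneTruth",
    "SyntheticTruth",
    "generate_genome",
    "simulate_fragments",
    "write_truth",
    "genome_records",
]

CHROM = "chrSim"


@dataclass
class IsoformTruth:
    transcript_id: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted
    expressed: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def pre_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def mat_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    isoforms: list[IsoformTruth]
    abundance: float  # relative molar abundance in Input
    pd_enrichment: float  # pull-down abundance multiplier
    phi_input: float  # unspliced molar fraction in Input
    phi_pd: float  # unspliced molar fraction in PD
    is_target: bool = False  # simulated RBP target

    def phi(self, condition: str) -> float:
        return self.phi_pd if condition == "PD" else self.phi_input


@dataclass
class SyntheticTruth:
    genes: list[GeneTruth]
    chrom_length: int
    seed: int
    params: dict = field(default_factory=dict)

    def targets(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_target]


def generate_genome(
    n_genes: int = 30,
    *,
    seed: int = 0,
    max_isoforms: int = 3,
    exon_count_range: tuple[int, int] = (3, 6),
    exon_length_range: tuple[int, int] = (600, 1000),
    intron_length_range: tuple[int, int] = (2500, 5000),
    alt_exon_fraction: float = 0.3,
    unexpressed_isoform_fraction: float = 0.2,
    overlap_fraction: float = 0.1,
    single_exon_fraction: float = 0.05,
    noncoding_fraction: float = 0.05,
    target_fraction: float = 0.25,
    pd_enrichment: float = 8.0,
    phi_input: float = 0.1,
    phi_pd_target: float = 0.4,
    intergenic_gap: int = 2000,
) -> SyntheticTruth:
    """Lay out ``n_genes`` genes with known isoform structure on one chromosome.

    A ``target_fraction`` of genes are simulated RBP targets: their molar
    abundance is multiplied by ``pd_enrichment`` in the pull-down and their
    unspliced fraction rises from ``phi_input`` to ``phi_pd_target`` there
    (the RBP binds pre-mRNA).  Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exon_length_range[0] < 1 or intron_length_range[0] < 1:
        raise ValueError("exon/intron lengths must be positive")
    rng = np.random.default_rng(seed)
    genes: list[GeneTruth] = []
    cursor = 1000
    prev_span: tuple[int, int, str] | None = None
    for gi in range(n_genes):
        gene_id = f"SIMG{gi:05d}.{1 + int(rng.integers(0, 9))}"  # versioned ID
        strand = "+" if rng.random() < 0.5 else "-"
        single_exon = rng.random() < single_exon_fraction
        n_exons = 1 if single_exon else int(rng.integers(*exon_count_range, endpoint=True))
        exon_lens = rng.integers(*exon_length_range, endpoint=True, size=n_exons)
        intron_lens = rng.integers(
            *intron_length_range, endpoint=True, size=max(n_exons - 1, 0)
        )
        overlap = prev_span is not None and rng.random() < overlap_fraction
        if overlap:
            # overlap the tail of the previous gene on the same strand, so
            # the collapse step sees a region claimed by two genes
            start = max(prev_span[1] - int(rng.integers(100, 400)), prev_span[0])
            strand = prev_span[2]
        else:
            start = cursor
        exons: list[tuple[int, int]] = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos = exons[-1][1]
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        base = IsoformTruth(transcript_id=f"{gene_id.split('.')[0]}T1", exons=exons)
        isoforms = [base]
        n_iso = 1 if single_exon else int(rng.integers(1, max_isoforms, endpoint=True))
        tnum = 2
        # alternatively spliced isoform: skip one internal exon
        if n_iso >= 2 and n_exons >= 3 and rng.random() < alt_exon_fraction:
            skip = int(rng.integers(1, n_exons - 1))
            isoforms.append(
                IsoformTruth(
                    transcript_id=f"{gene_id.split('.')[0]}T{tnum}",
                    exons=[ex for j, ex in enumerate(exons) if j != skip],
                )
            )
            tnum += 1
        # unexpressed isoform with an extra upstream exon (never covered)
        if rng.random() < unexpressed_isoform_fraction and not overlap and not single_exon:
            extra_len = int(rng.integers(*exon_length_range, endpoint=True))
            extra_start = start - int(rng.integers(*intron_length_range, endpoint=True))
            extra_start -= extra_len
            if extra_start > (prev_span[1] if prev_span else 0):
                isoforms.append(
                    IsoformTruth(
                        transcript_id=f"{gene_id.split('.')[0]}T{tnum}",
                        exons=[(extra_start, extra_start + extra_len)] + exons,
                        expressed=False,
                    )
                )
                tnum += 1
        is_target = rng.random() < target_fraction
        biotype = (
            "lncRNA" if rng.random() < noncoding_fraction else "protein_coding"
        )
        genes.append(
            GeneTruth(
                gene_id=gene_id,
                chrom=CHROM,
                strand=strand,
                biotype=biotype,
                isoforms=isoforms,
                abundance=float(rng.lognormal(0.0, 0.5)),
                pd_enrichment=pd_enrichment if is_target else 1.0,
                phi_input=phi_input,
                phi_pd=phi_pd_target if is_target else phi_input,
                is_target=is_target,
            )
        )
        gene_end = max(iso.span[1] for iso in isoforms)
        prev_span = (start, gene_end, strand)
        cursor = gene_end + intergenic_gap
    chrom_length = cursor + 10000
    params = {
        "n_genes": n_genes,
        "phi_input": phi_input,
        "phi_pd_target": phi_pd_target,
        "pd_enrichment": pd_enrichment,
    }
    return SyntheticTruth(genes=genes, chrom_length=chrom_length, seed=seed, params=params)


def genome_records(truth: SyntheticTruth) -> list[GtfRecord]:
    """Expand the truth into Ensembl-style exon GTF records."""
    records: list[GtfRecord] = []
    for gene in truth.genes:
        exon_ids: dict[tuple[int, int], str] = {}
        for iso in gene.isoforms:
            for s, e in iso.exons:
                exon_ids.setdefault((s, e), f"{gene.gene_id.split('.')[0]}E{len(exon_ids) + 1}")
        for iso in gene.isoforms:
            for s, e in iso.exons:
                records.append(
                    GtfRecord(
                        interval=GenomicInterval(gene.chrom, s, e, gene.strand),
                        source="simulated",
                        feature_type="exon",
                        attributes={
                            "gene_id": gene.gene_id,
                            "transcript_id": iso.transcript_id,
                            "exon_id": exon_ids[(s, e)],
                            "gene_biotype": gene.biotype,
                            "transcript_biotype": gene.biotype,
                        },
                    )
                )
    return records


def _transcript_to_genome(
    exons: Sequence[tuple[int, int]], t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(t_start - offset, 0), min(t_end - offset, length)
        if lo < hi:
            blocks.append((s + lo, s + hi))
        offset += length
    return blocks


def _cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ops: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            ops.append((3, gap))  # N
        ops.append((0, e - s))  # M
    return ops


def simulate_fragments(
    truth: SyntheticTruth,
    condition: str,
    n_fragments: int,
    out_path: str | Path,
    *,
    seed: int = 0,
    insert_size: int = 150,
    read_length: int = 60,
    strandedness: str = "reverse",
    phi_override: float | Mapping[str, float] | None = None,
    background_fraction: float = 0.0,
    sample_name: str | None = None,
) -> Path:
    """Draw fragments from the pre-mRNA/mRNA mixture and write name-sorted SAM.

    Per fragment: a molecule class (gene, expressed isoform, unspliced or
    spliced) is drawn with probability proportional to molar abundance x
    (PD enrichment if condition is PD) x molecule length — the length
    weighting implements fragmentation.  The fragment start is uniform on
    the molecule; unspliced molecules give contiguous genomic blocks,
    spliced molecules give junction-split blocks.  Mates are written as a
    properly paired, name-grouped SAM whose flags encode the configured
    strandedness.  A molecule shorter than the insert yields a fragment
    covering the whole molecule.
    """
    if condition not in ("PD", "Input"):
        raise ValueError(f"condition must be PD or Input, got {condition!r}")
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    rng = np.random.default_rng(seed)

    def _phi(gene: GeneTruth) -> float:
        if phi_override is None:
            return gene.phi(condition)
        if isinstance(phi_override, Mapping):
            return phi_override.get(gene.gene_id, gene.phi(condition))
        return float(phi_override)

    # enumerate molecule classes: (gene, isoform, unspliced?) with weights
    classes: list[tuple[GeneTruth, IsoformTruth, bool]] = []
    weights: list[float] = []
    for gene in truth.genes:
        expressed = [iso for iso in gene.isoforms if iso.expressed]
        if not expressed:
            continue
        molar = gene.abundance * (gene.pd_enrichment if condition == "PD" else 1.0)
        phi = _phi(gene)
        for iso in expressed:
            iso_molar = molar / len(expressed)
            if phi > 0:
                classes.append((gene, iso, True))
                weights.append(iso_molar * phi * iso.pre_length)
            if phi < 1:
                classes.append((gene, iso, False))
                weights.append(iso_molar * (1 - phi) * iso.mat_length)
    if not classes:
        raise ValueError("no expressed molecules to simulate")
    w = np.asarray(weights, dtype=float)
    w /= w.sum()

    n_background = int(round(n_fragments * background_fraction))
    n_genic = n_fragments - n_background
    draws = rng.choice(len(classes), size=n_genic, p=w)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": CHROM, "LN": int(truth.chrom_length)}],
        }
    )
    out_path = Path(out_path)
    frag_no = 0
    with pysam.AlignmentFile(str(out_path), "w", header=header) as sam:
        def _write_pair(blocks: list[tuple[int, int]], gene_strand: str) -> None:
            nonlocal frag_no
            total = sum(e - s for s, e in blocks)
            # mate1 covers the first read_length bases of the fragment,
            # mate2 the last read_length (in genomic orientation)
            r1_blocks = _clip(blocks, 0, min(read_length, total))
            r2_blocks = _clip(blocks, max(total - read_length, 0), total)
            name = f"frag{frag_no:08d}"
            frag_no += 1
            if strandedness == "reverse":
                mate1_reverse = gene_strand == "+"
            elif strandedness == "forward":
                mate1_reverse = gene_strand == "-"
            else:
                mate1_reverse = bool(rng.random() < 0.5)
            for which, blk, rev in (
                (1, r1_blocks, mate1_reverse),
                (2, r2_blocks, not mate1_reverse),
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.flag = (
                    0x1
                    | 0x2
                    | (0x40 if which == 1 else 0x80)
                    | (0x10 if rev else 0)
                    | (0x20 if not rev else 0)
                )
                a.reference_id = 0
                a.reference_start = blk[0][0]
                a.mapping_quality = 60
                a.cigartuples = _cigar(blk)
                rl = sum(e - s for s, e in blk)
                a.query_sequence = "N" * rl
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                other = r2_blocks if which == 1 else r1_blocks
                a.next_reference_id = 0
                a.next_reference_start = other[0][0]
                tlen = blocks[-1][1] - blocks[0][0]
                a.template_length = tlen if blk[0][0] <= other[0][0] else -tlen
                sam.write(a)

        for ci in draws:
            gene, iso, unspliced = classes[ci]
            if unspliced:
                mol_len = iso.pre_length
            else:
                mol_len = iso.mat_length
            flen = min(insert_size, mol_len)
            start = int(rng.integers(0, mol_len - flen + 1))
            if unspliced:
                g0 = iso.span[0]
                blocks = [(g0 + start, g0 + start + flen)]
            else:
                blocks = _transcript_to_genome(iso.exons, start, start + flen)
            _write_pair(blocks, gene.strand)

        # intergenic background fragments (exercise the unassigned path)
        for _ in range(n_background):
            pos = int(rng.integers(0, truth.chrom_length - insert_size))
            strand = "+" if rng.random() < 0.5 else "-"
            _write_pair([(pos, pos + insert_size)], strand)
    return out_path


def _clip(
    blocks: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Sub-blocks covering fragment-coordinate range [lo, hi)."""
    out: list[tuple[int, int]] = []
    offset = 0
    for s, e in blocks:
        length = e - s
        a, b = max(lo - offset, 0), min(hi - offset, length)
        if a < b:
            out.append((s + a, s + b))
        offset += length
    return out


def write_truth(truth: SyntheticTruth, path: str | Path) -> pd.DataFrame:
    """Flatten the truth to a per-isoform TSV for test assertions."""
    rows = []
    for gene in truth.genes:
        for iso in gene.isoforms:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "transcript_id": iso.transcript_id,
                    "chrom": gene.chrom,
                    "strand": gene.strand,
                    "biotype": gene.biotype,
                    "exons": ";".join(f"{s}-{e}" for s, e in iso.exons),
                    "expressed": iso.expressed,
                    "abundance": gene.abundance,
                    "pd_enrichment": gene.pd_enrichment,
                    "phi_input": gene.phi_input,
                    "phi_pd": gene.phi_pd,
                    "is_target": gene.is_target,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
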