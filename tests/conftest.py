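"""Shared fixtures: random toy genomes, tiny SAM writers, design sheets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from inextools.annotation import TranscriptModel
from inextools.gtf_io import GenomicInterval, GtfRecord
from inextools.quantify import SampleDesign


def exon_record(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    gene: str,
    transcript: str,
    exon: str,
    biotype: str = "protein_coding",
) -> GtfRecord:
    return GtfRecord(
        interval=GenomicInterval(chrom, start, end, strand),
        source="test",
        feature_type="exon",
        attributes={
            "gene_id": gene,
            "transcript_id": transcript,
            "exon_id": exon,
            "gene_biotype": biotype,
        },
    )


def random_toy_genome(rng: np.random.Generator, n_genes: int | None = None):
    """A deliberately messy toy genome for the annotation builder.

    Genes land at random positions (overlaps arise by chance), each with
    1-5 transcript variants assembled from a shared backbone of alternating
    segments; a variant uses a random subset of the backbone exons and may
    add a cassette exon inside a backbone intron, creating
    exon-in-one/intron-in-another ambiguity.  Returns exon GtfRecords, a
    synthetic coverage map (two samples), and the list of transcripts the
    coverage filter should retain.
    """
    if n_genes is None:
        n_genes = int(rng.integers(2, 21))
    records: list[GtfRecord] = []
    used_ids: set[str] = set()
    retained: list[TranscriptModel] = []
    for gi in range(n_genes):
        gene = f"G{gi}"
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(0, 30_000))
        n_seg = int(rng.integers(2, 7))
        backbone: list[tuple[int, int]] = []
        for _ in range(n_seg):
            length = int(rng.integers(20, 200))
            backbone.append((pos, pos + length))
            pos += length + int(rng.integers(0, 300))  # gap may be 0 (touching)
        cassette_pool: list[tuple[int, int]] = []
        for (s1, e1), (s2, _) in zip(backbone, backbone[1:]):
            if s2 - e1 >= 40:
                mid = e1 + int(rng.integers(10, s2 - e1 - 20))
                cassette_pool.append((mid, mid + int(rng.integers(10, min(s2 - mid, 100)))))
        exon_ids: dict[tuple[int, int], str] = {}

        def _eid(iv: tuple[int, int]) -> str:
            return exon_ids.setdefault(iv, f"{gene}E{len(exon_ids)}")

        n_tv = int(rng.integers(1, 6))
        gene_tvs: list[tuple[str, list[tuple[int, int]]]] = []
        for ti in range(n_tv):
            take = [iv for iv in backbone if rng.random() < 0.8]
            if not take:
                take = [backbone[0]]
            if cassette_pool and rng.random() < 0.4:
                take.append(cassette_pool[int(rng.integers(len(cassette_pool)))])
            take.sort()
            gene_tvs.append((f"{gene}T{ti}", take))
        covered_ids = {
            _eid(iv)
            for _, tv in gene_tvs
            for iv in tv
            if rng.random() < 0.85
        }
        used_ids |= covered_ids
        for tid, ivs in gene_tvs:
            recs = [
                exon_record("chrT", s, e, strand, gene, tid, _eid((s, e)))
                for s, e in ivs
            ]
            records.extend(recs)
            if all(_eid(iv) in covered_ids for iv in ivs):
                retained.append(
                    TranscriptModel(transcript_id=tid, gene_id=gene, exons=recs)
                )
    # split the used set across two samples, union must restore it
    ids = sorted(used_ids)
    half = len(ids) // 2
    per_exon_counts = {
        "Input_1": {i: 1 for i in ids[:half]},
        "PD_1": {i: (2 if i in ids[half:] else 0) for i in ids},
    }
    return records, per_exon_counts, retained


def write_sam(path, reads, chrom="chrT", chrom_len=1_000_000):
    """Write a minimal name-grouped SAM.

    ``reads``: iterables of (name, flag, pos, cigar) in 0-based coordinates.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, flag, pos, cigar in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            qlen = a.infer_query_length()
            a.query_sequence = "N" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            fh.write(a)
    return path


@pytest.fixture
def design_3v3() -> SampleDesign:
    rows = [
        {"sample": f"{c}_{r}", "condition": c, "replicate": str(r)}
        for c in ("PD", "Input")
        for r in (1, 2, 3)
    ]
    return SampleDesign.from_frame(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
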