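"""Build a non-redundant, unambiguous per-gene exon/intron reference.

Raw annotations are ambiguous about what is "intron": with alternative
splicing the same stretch of genome can sit inside the mature mRNA of one
transcript variant and inside an intron of another.  Counting pre-mRNA
signal on such regions would contaminate the (low) intronic signal with the
far more abundant exonic signal.  The builder therefore

1. keeps only exons of protein-coding transcript variants (optional),
2. drops transcript variants with any exon lacking fragment coverage in
   every sample (unexpressed variants),
3. derives introns as the gaps between consecutive exons of each retained
   variant,
4. subtracts, strand-aware, exon from intron annotations and vice versa so
   that no base is both,
5. collapses overlapping/touching same-type annotations per strand and
   discards anything claimed by more than one gene,
6. tabulates total unambiguous intron/exon length per gene.

The result is a reference in which every base belongs to at most one gene
and is unambiguously exonic or intronic for that gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .gtf_io import GenomicInterval, GtfRecord

__all__ = [
    "TranscriptModel",
    "AnnotationSet",
    "filter_protein_coding_exons",
    "used_exon_ids",
    "group_transcripts",
    "filter_fully_covered_transcripts",
    "derive_introns",
    "subtract_ambiguous",
    "collapse_and_merge",
    "compute_length_table",
    "build_reference",
]

logger = logging.getLogger(__name__)

PROTEIN_CODING_BIOTYPES = frozenset({"protein_coding", "protein_coding_LoF"})


@dataclass
class TranscriptModel:
    """One transcript variant: position-sorted, non-overlapping exons."""

    transcript_id: str
    gene_id: str
    exons: list[GtfRecord] = field(default_factory=list)

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        ivs = [e.interval for e in self.exons]
        chroms = {iv.chrom for iv in ivs}
        strands = {iv.strand for iv in ivs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans multiple chromosomes/strands"
            )
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons not sorted by start"
                )
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap "
                    f"([{a.start},{a.end}) and [{b.start},{b.end}))"
                )


@dataclass
class AnnotationSet:
    """Final unambiguous reference: exon and intron features, one gene each."""

    features: list[GtfRecord] = field(default_factory=list)

    def by_type(self, feature_type: str) -> list[GtfRecord]:
        return [f for f in self.features if f.feature_type == feature_type]

    def by_gene(self) -> dict[str, list[GtfRecord]]:
        out: dict[str, list[GtfRecord]] = {}
        for f in self.features:
            out.setdefault(f.gene_id, []).append(f)
        return out

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GtfRecord]:
        return iter(self.features)


def filter_protein_coding_exons(
    records: Iterable[GtfRecord],
    biotypes: frozenset[str] = PROTEIN_CODING_BIOTYPES,
) -> Iterator[GtfRecord]:
    """Keep exon records whose biotype attribute is protein-coding.

    Any attribute key ending in ``biotype`` (gene_biotype,
    transcript_biotype) qualifies, matching the usual Ensembl layout.
    Order is preserved.
    """
    for rec in records:
        if rec.feature_type != "exon":
            continue
        values = {v for k, v in rec.attributes.items() if k.endswith("biotype")}
        if values & biotypes:
            yield rec


def used_exon_ids(per_exon_counts: Mapping[str, Mapping[str, int]]) -> set[str]:
    """Union, over samples, of exon IDs with a fragment count > 0."""
    used: set[str] = set()
    for counts in per_exon_counts.values():
        used.update(eid for eid, n in counts.items() if n > 0)
    return used


def group_transcripts(records: Iterable[GtfRecord]) -> list[TranscriptModel]:
    """Group exon records into transcript models, exons sorted by position."""
    by_tid: dict[str, TranscriptModel] = {}
    for rec in records:
        tid = rec.attributes.get("transcript_id")
        if tid is None:
            raise ValueError("exon record lacks transcript_id")
        model = by_tid.setdefault(
            tid, TranscriptModel(transcript_id=tid, gene_id=rec.gene_id)
        )
        model.exons.append(rec)
    for model in by_tid.values():
        model.exons.sort(key=lambda r: (r.interval.start, r.interval.end))
        model.validate()
    return sorted(by_tid.values(), key=lambda m: m.transcript_id)


def filter_fully_covered_transcripts(
    transcripts: Sequence[TranscriptModel], used: set[str]
) -> list[TranscriptModel]:
    """Retain a transcript iff every one of its exon IDs saw coverage.

    The criterion is the count comparison "exons with coverage == total
    exons", evaluated on exon IDs, so an unexpressed variant distinguished
    only by one uncovered exon is dropped while variants sharing all their
    covered exons survive.
    """
    kept = []
    for tv in transcripts:
        ids = [e.attributes.get("exon_id") for e in tv.exons]
        if any(i is None for i in ids):
            raise ValueError(
                f"transcript {tv.transcript_id}: exon without exon_id attribute"
            )
        if sum(i in used for i in ids) == len(ids):
            kept.append(tv)
    return kept


def derive_introns(transcript: TranscriptModel) -> list[GtfRecord]:
    """Introns = gaps between consecutive exons of one transcript variant.

    Emits exactly n_exons - 1 introns unless adjacent exons touch (gap of
    zero bases), in which case no intron is emitted for that junction.
    Introns inherit chrom/strand and the gene/transcript identity; their
    source is marked ``calculated``.
    """
    transcript.validate()
    introns: list[GtfRecord] = []
    exons = transcript.exons
    for prev, nxt in zip(exons, exons[1:]):
        gap_start, gap_end = prev.interval.end, nxt.interval.start
        if gap_end <= gap_start:
            continue
        attrs = {"gene_id": transcript.gene_id, "transcript_id": transcript.transcript_id}
        introns.append(
            GtfRecord(
                interval=GenomicInterval(
                    prev.interval.chrom, gap_start, gap_end, prev.interval.strand
                ),
                source="calculated",
                feature_type="intron",
                attributes=attrs,
            )
        )
    return introns


def _subtract_one(
    iv: GenomicInterval, cuts: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """iv minus the union of same-strand cuts; may split into pieces."""
    pieces = [(iv.start, iv.end)]
    for cut in cuts:
        if cut.chrom != iv.chrom or cut.strand != iv.strand:
            continue
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if cut.end <= s or cut.start >= e:
                nxt.append((s, e))
                continue
            if cut.start > s:
                nxt.append((s, cut.start))
            if cut.end < e:
                nxt.append((cut.end, e))
        pieces = nxt
        if not pieces:
            break
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces]


def subtract_ambiguous(
    exons: Sequence[GtfRecord], introns: Sequence[GtfRecord]
) -> tuple[list[GtfRecord], list[GtfRecord]]:
    """Strand-aware reciprocal subtraction of exon and intron annotations.

    A region that is exonic in one transcript variant and intronic in
    another is ambiguous and removed from both sides; opposite-strand
    overlaps are ignored.  Intervals may be split by the subtraction.
    """

    def _index(records: Sequence[GtfRecord]) -> dict[tuple[str, str], list[GenomicInterval]]:
        idx: dict[tuple[str, str], list[GenomicInterval]] = {}
        for r in records:
            idx.setdefault((r.interval.chrom, r.interval.strand), []).append(r.interval)
        for lst in idx.values():
            lst.sort()
        return idx

    def _cut(records: Sequence[GtfRecord], cutter) -> list[GtfRecord]:
        out: list[GtfRecord] = []
        for rec in records:
            key = (rec.interval.chrom, rec.interval.strand)
            relevant = [
                c
                for c in cutter.get(key, [])
                if c.start < rec.interval.end and c.end > rec.interval.start
            ]
            for piece in _subtract_one(rec.interval, relevant):
                out.append(
                    GtfRecord(
                        interval=piece,
                        source=rec.source,
                        feature_type=rec.feature_type,
                        score=rec.score,
                        frame=rec.frame,
                        attributes=dict(rec.attributes),
                    )
                )
        return out

    exon_idx, intron_idx = _index(exons), _index(introns)
    return _cut(exons, intron_idx), _cut(introns, exon_idx)


def collapse_and_merge(features: Sequence[GtfRecord]) -> AnnotationSet:
    """Collapse per-type annotations and drop regions shared between genes.

    Same-strand, same-feature-type intervals that overlap or touch are
    merged (touching counts as mergeable, as in the reference interval
    toolkit's merge); the merged feature collects the distinct gene IDs of
    its constituents, and any merged feature claimed by more than one gene
    is discarded outright.
    """
    out: list[GtfRecord] = []
    for ftype in ("exon", "intron"):
        grouped: dict[tuple[str, str], list[GtfRecord]] = {}
        for rec in features:
            if rec.feature_type != ftype:
                continue
            grouped.setdefault((rec.interval.chrom, rec.interval.strand), []).append(rec)
        for (chrom, strand), recs in sorted(grouped.items()):
            recs.sort(key=lambda r: (r.interval.start, r.interval.end))
            cur_start = cur_end = None
            cur_genes: set[str] = set()
            merged: list[tuple[int, int, set[str]]] = []
            for rec in recs:
                s, e = rec.interval.start, rec.interval.end
                if cur_end is None:
                    cur_start, cur_end, cur_genes = s, e, {rec.gene_id}
                elif s <= cur_end:  # overlap or touch
                    cur_end = max(cur_end, e)
                    cur_genes.add(rec.gene_id)
                else:
                    merged.append((cur_start, cur_end, cur_genes))
                    cur_start, cur_end, cur_genes = s, e, {rec.gene_id}
            if cur_end is not None:
                merged.append((cur_start, cur_end, cur_genes))
            for s, e, genes in merged:
                if len(genes) > 1:
                    continue
                out.append(
                    GtfRecord(
                        interval=GenomicInterval(chrom, s, e, strand),
                        source=".",
                        feature_type=ftype,
                        attributes={"gene_id": next(iter(genes))},
                    )
                )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.feature_type))
    return AnnotationSet(features=out)


def compute_length_table(annotation: AnnotationSet) -> pd.DataFrame:
    """Per-gene total unambiguous intron/exon length.

    Columns ``in_length`` and ``ex_length``, indexed by ``gene_id``.  Genes
    with no intron feature get in_length 0 (single-exon genes; excluded
    later at length normalization).
    """
    rows: dict[str, dict[str, int]] = {}
    for rec in annotation:
        entry = rows.setdefault(rec.gene_id, {"in_length": 0, "ex_length": 0})
        key = "in_length" if rec.feature_type == "intron" else "ex_length"
        entry[key] += len(rec.interval)
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        df = pd.DataFrame(columns=["in_length", "ex_length"], dtype=int)
    df.index.name = "gene_id"
    return df[["in_length", "ex_length"]].sort_index()


def build_reference(
    records: Iterable[GtfRecord],
    per_exon_counts: Mapping[str, Mapping[str, int]] | None = None,
    *,
    protein_coding_filter: bool = True,
    strict_checks: bool = False,
) -> tuple[AnnotationSet, pd.DataFrame]:
    """Run the full reference-building chain on parsed GTF records.

    ``per_exon_counts`` carries the coverage evidence (per sample, per
    exon_id fragment counts, union mode with multi-feature fragments counted
    for every feature).  ``None`` skips the expression filter, treating every
    transcript variant as expressed.  With ``strict_checks`` the directional
    sanity checks (intron annotation count must not drop during subtraction,
    exon count must not rise) raise instead of merely logging.
    """
    records = list(records)
    if protein_coding_filter:
        exon_records = list(filter_protein_coding_exons(records))
    else:
        exon_records = [r for r in records if r.feature_type == "exon"]
    transcripts = group_transcripts(exon_records)
    if per_exon_counts is not None:
        used = used_exon_ids(per_exon_counts)
        transcripts = filter_fully_covered_transcripts(transcripts, used)
    logger.info("retained %d expressed transcript variants", len(transcripts))

    exons = [e for tv in transcripts for e in tv.exons]
    introns = [i for tv in transcripts for i in derive_introns(tv)]
    n_ex_in, n_in_in = len(exons), len(introns)

    exons_u, introns_u = subtract_ambiguous(exons, introns)
    if len(introns_u) < n_in_in or len(exons_u) > n_ex_in:
        msg = (
            "subtraction sanity check failed: expected intron annotations to "
            f"increase ({n_in_in}->{len(introns_u)}) and exon annotations to "
            f"decrease ({n_ex_in}->{len(exons_u)})"
        )
        if strict_checks:
            raise AssertionError(msg)
        logger.warning(msg)

    annotation = collapse_and_merge(exons_u + introns_u)
    lengths = compute_length_table(annotation)
    return annotation, lengths
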