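"""Per-gene (or per-exon) fragment counting on stranded paired-end input.

A *fragment* is a sequenced cDNA molecule, represented by the union of the
aligned blocks of its read pair.  Counting reproduces the two classic
overlap-resolution modes:

union
    a fragment counts for every feature it overlaps by at least one aligned
    base (multi-feature fragments count once per feature);
intersection-strict
    a fragment counts for a feature only if *every* aligned base lies inside
    that feature's intervals; junction gaps (CIGAR ``N``) and the unspanned
    insert between mates impose no constraint.

Applied to the unambiguous annotation, the three standard invocations are
(intron features, union) for intronic fragments — introns plus exon-intron
boundaries; (exon features, union) for exonic fragments; and (exon
features, intersection-strict) for strictly exonic fragments — exons and
exon-exon junctions only.  The intron-union and exon-strict categories are
disjoint per gene, which is what makes their sum a valid library size.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .gtf_io import GtfRecord

__all__ = [
    "Fragment",
    "FeatureIndex",
    "assemble_fragments",
    "classify_union",
    "classify_intersection_strict",
    "count_fragments",
]

logger = logging.getLogger(__name__)

STRANDEDNESS_MODES = ("reverse", "forward", "unstranded")


@dataclass
class Fragment:
    """Union of the aligned blocks of one read pair (or singleton)."""

    query_name: str
    chrom: str
    blocks: list[tuple[int, int]]  # sorted, non-overlapping, half-open
    library_strand: str | None  # None under unstranded counting

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def _merge_blocks(blocks: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open blocks; overlapping or touching runs coalesce."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _infer_strand(reads: Sequence, strandedness: str) -> str | None:
    """Transcriptional strand of the fragment under the library protocol.

    ``reverse``: mate 1 aligns antisense to the transcript, so the library
    strand is the opposite of mate 1's (equivalently mate 2's) alignment
    strand.  ``forward`` is the mirror image.  ``unstranded`` returns None.
    """
    if strandedness == "unstranded":
        return None
    mate1 = next((r for r in reads if not r.is_read2), reads[0])
    aligned_strand = "-" if mate1.is_reverse else "+"
    if strandedness == "reverse":
        return "-" if aligned_strand == "+" else "+"
    return aligned_strand


def assemble_fragments(
    alignments: str | Path | pysam.AlignmentFile,
    strandedness: str = "reverse",
) -> Iterator[Fragment]:
    """Combine name-grouped primary alignments into fragments.

    Input must be name-sorted (mates adjacent); a query name recurring after
    its group has closed raises.  Secondary, supplementary and unmapped
    records are ignored; pairs whose mates map to different chromosomes are
    skipped with a warning.
    """
    if strandedness not in STRANDEDNESS_MODES:
        raise ValueError(f"unknown strandedness {strandedness!r}")
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        seen: set[str] = set()
        group: list = []

        def _finish(reads: list) -> Fragment | None:
            chroms = {r.reference_name for r in reads}
            if len(chroms) > 1:
                logger.warning(
                    "skipping chimeric pair %s mapped to %s",
                    reads[0].query_name,
                    sorted(chroms),
                )
                return None
            blocks = _merge_blocks(b for r in reads for b in r.get_blocks())
            if not blocks:
                return None
            return Fragment(
                query_name=reads[0].query_name,
                chrom=chroms.pop(),
                blocks=blocks,
                library_strand=_infer_strand(reads, strandedness),
            )

        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if group and read.query_name != group[0].query_name:
                seen.add(group[0].query_name)
                frag = _finish(group)
                if frag is not None:
                    yield frag
                group = []
            if not group and read.query_name in seen:
                raise ValueError(
                    f"input not name-sorted: query {read.query_name!r} recurs "
                    "after its mate group closed"
                )
            group.append(read)
        if group:
            frag = _finish(group)
            if frag is not None:
                yield frag
    finally:
        if own:
            alignments.close()


class FeatureIndex:
    """Overlap and coverage queries over one feature type, keyed by ID."""

    def __init__(self, features: Iterable[GtfRecord], key: str = "gene_id"):
        self.key = key
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        raw: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
        self.keys: list[str] = []
        seen_keys: set[str] = set()
        for rec in features:
            kv = rec.attributes.get(key)
            if kv is None:
                raise ValueError(f"feature lacks {key!r} attribute")
            if kv not in seen_keys:
                seen_keys.add(kv)
                self.keys.append(kv)
            iv = rec.interval
            self._trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
                iv.start, iv.end, kv
            )
            raw.setdefault((kv, iv.chrom, iv.strand), []).append((iv.start, iv.end))
            raw.setdefault((kv, iv.chrom, "*"), []).append((iv.start, iv.end))
        if not self.keys:
            raise ValueError("empty feature set")
        # merged per-key interval lists for O(log n) containment checks
        self._cover: dict[tuple[str, str, str], tuple[list[int], list[int]]] = {}
        for k, blocks in raw.items():
            merged = _merge_blocks(blocks)
            self._cover[k] = ([s for s, _ in merged], [e for _, e in merged])

    def _strands(self, library_strand: str | None) -> tuple[str, ...]:
        return ("+", "-") if library_strand is None else (library_strand,)

    def overlapping(self, fragment: Fragment) -> set[str]:
        hits: set[str] = set()
        for strand in self._strands(fragment.library_strand):
            tree = self._trees.get((fragment.chrom, strand))
            if tree is None:
                continue
            for s, e in fragment.blocks:
                hits.update(iv.data for iv in tree.overlap(s, e))
        return hits

    def covers(self, key_value: str, fragment: Fragment) -> bool:
        """True iff every aligned base of the fragment lies in this key."""
        strand = "*" if fragment.library_strand is None else fragment.library_strand
        cover = self._cover.get((key_value, fragment.chrom, strand))
        if cover is None:
            return False
        starts, ends = cover
        for s, e in fragment.blocks:
            i = bisect_right(starts, s) - 1
            if i < 0 or ends[i] < e:
                return False
        return True


def classify_union(fragment: Fragment, index: FeatureIndex) -> set[str]:
    """Keys of all matching-strand features overlapping >=1 aligned base."""
    return index.overlapping(fragment)


def classify_intersection_strict(fragment: Fragment, index: FeatureIndex) -> set[str]:
    """Intersection over aligned bases of the covering key sets.

    Equivalently: the keys whose feature intervals cover every aligned base
    of the fragment.  Any aligned base outside all features empties the
    result; junction gaps impose no constraint.
    """
    return {k for k in index.overlapping(fragment) if index.covers(k, fragment)}


def count_fragments(
    alignments: str | Path | pysam.AlignmentFile,
    features: Iterable[GtfRecord],
    *,
    mode: str = "union",
    key: str = "gene_id",
    strandedness: str = "reverse",
) -> pd.Series:
    """One count column: fragments per key value under the chosen mode.

    Every key value present in the feature set appears in the output, with
    count 0 if nothing mapped to it.  Multi-feature fragments increment every
    key in their classification set (the nonunique-all convention) — required
    so that a fragment overlapping two genes, or one shared exon of several
    transcripts, is counted for each.
    """
    if mode not in ("union", "intersection_strict"):
        raise ValueError(f"unknown mode {mode!r}")
    index = FeatureIndex(features, key=key)
    classify = classify_union if mode == "union" else classify_intersection_strict
    counts = dict.fromkeys(index.keys, 0)
    for frag in assemble_fragments(alignments, strandedness=strandedness):
        for k in classify(frag, index):
            counts[k] += 1
    return pd.Series(counts, name="count", dtype=int)
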