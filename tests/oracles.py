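"""Brute-force per-base oracles, independent of the package's algorithms.

Everything here works by enumerating genomic positions and applying the
definitions literally; nothing touches interval trees, bisection or the
package's subtraction/merge code paths.
"""

from __future__ import annotations

from collections import defaultdict

from inextools.gtf_io import GtfRecord


def label_reference(transcripts) -> set[tuple[str, str, int, int, str, str]]:
    """Expected unambiguous annotation as (chrom, strand, start, end, type, gene).

    Per strand: a base is exonic for gene g if it lies in an exon of any of
    g's retained transcript variants, intronic likewise for the gaps between
    consecutive exons.  A base both exonic and intronic for *any* genes on
    the strand is ambiguous and removed from both labels.  The surviving
    per-type coverage is split into maximal runs of consecutive bases
    (touching runs coalesce, as interval merging does); a run fed by more
    than one gene is discarded whole, mirroring the merge-then-drop of
    multi-gene rows.
    """
    # per (chrom, strand): base -> set of genes claiming it as exon / intron
    ex_claims: dict[tuple[str, str], dict[int, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    in_claims: dict[tuple[str, str], dict[int, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for tv in transcripts:
        iv0 = tv.exons[0].interval
        key = (iv0.chrom, iv0.strand)
        for exon in tv.exons:
            for b in range(exon.interval.start, exon.interval.end):
                ex_claims[key][b].add(tv.gene_id)
        for a, b_ in zip(tv.exons, tv.exons[1:]):
            for b in range(a.interval.end, b_.interval.start):
                in_claims[key][b].add(tv.gene_id)

    expected: set[tuple[str, str, int, int, str, str]] = set()
    for key in set(ex_claims) | set(in_claims):
        chrom, strand = key
        ex, intr = ex_claims[key], in_claims[key]
        for ftype, mine, other in (("exon", ex, intr), ("intron", intr, ex)):
            surviving = {b: g for b, g in mine.items() if b not in other}
            for start, end, genes in _runs(surviving):
                if len(genes) == 1:
                    expected.add((chrom, strand, start, end, ftype, next(iter(genes))))
    return expected


def _runs(base_genes: dict[int, set[str]]):
    """Maximal runs of consecutive bases with the union of their gene sets."""
    if not base_genes:
        return
    positions = sorted(base_genes)
    start = prev = positions[0]
    genes = set(base_genes[start])
    for b in positions[1:]:
        if b == prev + 1:
            genes |= base_genes[b]
        else:
            yield start, prev + 1, genes
            start, genes = b, set(base_genes[b])
        prev = b
    yield start, prev + 1, genes


def annotation_to_tuples(annotation) -> set[tuple[str, str, int, int, str, str]]:
    return {
        (
            r.interval.chrom,
            r.interval.strand,
            r.interval.start,
            r.interval.end,
            r.feature_type,
            r.gene_id,
        )
        for r in annotation
    }


def classify_union_bruteforce(fragment, features: list[GtfRecord], key: str) -> set[str]:
    """Keys of matching-strand features overlapping >=1 aligned base."""
    hits = set()
    for rec in features:
        iv = rec.interval
        if iv.chrom != fragment.chrom:
            continue
        if fragment.library_strand is not None and iv.strand != fragment.library_strand:
            continue
        for s, e in fragment.blocks:
            if iv.start < e and s < iv.end:
                hits.add(rec.attributes[key])
                break
    return hits


def classify_strict_bruteforce(fragment, features: list[GtfRecord], key: str) -> set[str]:
    """Per-base set intersection: keys covering every aligned base."""
    result: set[str] | None = None
    for s, e in fragment.blocks:
        for b in range(s, e):
            covering = set()
            for rec in features:
                iv = rec.interval
                if iv.chrom != fragment.chrom:
                    continue
                if (
                    fragment.library_strand is not None
                    and iv.strand != fragment.library_strand
                ):
                    continue
                if iv.start <= b < iv.end:
                    covering.add(rec.attributes[key])
            result = covering if result is None else (result & covering)
            if not result:
                return set()
    return result or set()


def length_table_bruteforce(annotation) -> dict[str, tuple[int, int]]:
    """Per-gene (in_length, ex_length) by counting bases one at a time."""
    out: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for rec in annotation:
        idx = 0 if rec.feature_type == "intron" else 1
        out[rec.gene_id][idx] += sum(
            1 for _ in range(rec.interval.start, rec.interval.end)
        )
    return {g: (v[0], v[1]) for g, v in out.items()}


def welch_p_bruteforce(a, b) -> float:
    """Closed-form Welch statistic + t CDF, independent of scipy.ttest_ind."""
    import math

    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * float(tdist.sf(abs(t), df))


def bh_bruteforce(pvals) -> list[float]:
    """Step-up BH: sort, p*m/rank, enforce monotone from the largest, cap."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    scaled = [pvals[i] * m / (rank + 1) for rank, i in enumerate(order)]
    for r in range(m - 2, -1, -1):
        scaled[r] = min(scaled[r], scaled[r + 1])
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = min(scaled[rank], 1.0)
    return out
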