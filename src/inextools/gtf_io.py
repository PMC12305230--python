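"""GTF/BED input and output and the coordinate conventions that go with them.

All intervals inside the package are 0-based half-open on an explicit strand.
GTF (1-based closed) and BED (0-based half-open) conversions happen only in
this module, at the I/O boundary, so the rest of the pipeline never does
plus/minus-one arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "GtfRecord",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "to_bed",
    "from_bed",
    "strip_version",
]

STRANDS = ("+", "-")

_FEATURE_TYPES = ("exon", "intron")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GtfRecord:
    """One exon or intron feature with its Ensembl-style attributes.

    ``attributes`` is an ordered mapping; ``gene_id`` is mandatory for
    everything downstream of parsing.
    """

    interval: GenomicInterval
    source: str = "."
    feature_type: str = "exon"
    score: str = "."
    frame: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in _FEATURE_TYPES:
            raise ValueError(
                f"feature_type must be one of {_FEATURE_TYPES}, got {self.feature_type!r}"
            )

    @property
    def gene_id(self) -> str:
        return self.attributes["gene_id"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GtfRecord):
            return NotImplemented
        return (
            self.interval == other.interval
            and self.source == other.source
            and self.feature_type == other.feature_type
            and self.attributes == other.attributes
        )


class GtfParseError(ValueError):
    """Raised for malformed GTF/BED lines; message names the line number."""


_ATTR_RE = re.compile(r'\s*([^\s"]+)\s+"?([^";]*?)"?\s*(?:;|$)')


def _parse_attributes(col9: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(col9):
        key, value = m.group(1), m.group(2)
        if not key:
            continue
        if key in attrs:
            raise GtfParseError(f"line {line_no}: duplicate attribute key {key!r}")
        attrs[key] = value
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def parse_gtf(
    path: str | Path, *, feature_types: Sequence[str] | None = None
) -> Iterator[GtfRecord]:
    """Yield :class:`GtfRecord` per feature line of an Ensembl-dialect GTF.

    Coordinates are converted from GTF's 1-based closed convention to the
    internal 0-based half-open one (start = col4 - 1, end = col5).  Lines
    whose feature type is neither ``exon`` nor ``intron`` (CDS, gene,
    transcript, ...) are skipped unless ``feature_types`` widens/narrows the
    accepted set — the pipeline only ever consumes the two.

    Raises :class:`GtfParseError` naming the offending line on malformed
    input (fewer than 9 tab fields, non-integer coordinates, start > end,
    strand other than + or -).
    """
    accept = set(feature_types) if feature_types is not None else set(_FEATURE_TYPES)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {line_no}: expected >=9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, ftype, c4, c5, score, strand, frame, col9 = fields[:9]
            if ftype not in accept:
                continue
            try:
                start, end = int(c4) - 1, int(c5)
            except ValueError:
                raise GtfParseError(
                    f"line {line_no}: non-integer coordinates {c4!r}, {c5!r}"
                ) from None
            if start >= end:
                raise GtfParseError(
                    f"line {line_no}: start must not exceed end ({c4} > {c5})"
                )
            if strand not in STRANDS:
                raise GtfParseError(
                    f"line {line_no}: strand must be '+' or '-', got {strand!r} "
                    "(every downstream step is strand-aware)"
                )
            yield GtfRecord(
                interval=GenomicInterval(chrom, start, end, strand),
                source=source,
                feature_type=ftype,
                score=score,
                frame=frame,
                attributes=_parse_attributes(col9, line_no),
            )


def write_gtf(records: Iterable[GtfRecord], path: str | Path) -> None:
    """Write records as 9-column GTF, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        rec.source,
                        rec.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        rec.score,
                        iv.strand,
                        rec.frame,
                        _format_attributes(rec.attributes),
                    )
                )
                + "\n"
            )


def to_bed(record: GtfRecord) -> tuple[str, int, int, str, str, str]:
    """BED6 row (chrom, start, end, gene_id, '.', strand), 0-based half-open."""
    if "gene_id" not in record.attributes:
        raise ValueError("record has no gene_id attribute")
    iv = record.interval
    return (iv.chrom, iv.start, iv.end, record.attributes["gene_id"], ".", iv.strand)


def from_bed(
    row: Sequence, feature_type: str = "exon", source: str = "."
) -> GtfRecord:
    """Inverse of :func:`to_bed` (feature type is not encoded in BED6)."""
    chrom, start, end, name, score, strand = row[:6]
    return GtfRecord(
        interval=GenomicInterval(chrom, int(start), int(end), strand),
        source=source,
        feature_type=feature_type,
        score=str(score),
        attributes={"gene_id": name},
    )


_VERSION_RE = re.compile(r"\.[0-9]+$")


def strip_version(identifier: str) -> str:
    """Drop a trailing ``.<digits>`` version suffix from an Ensembl ID."""
    return _VERSION_RE.sub("", identifier)
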