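"""Count-table assembly and normalization.

Library size here is *not* the total number of aligned fragments: it is the
per-sample sum of intronic (union) and strictly exonic
(intersection-strict) counts.  Both the intronic and the exonic categories
include exon-intron boundary fragments, so summing intron-union and
exon-union would count those twice; intron-union plus exon-strict counts
every assigned fragment exactly once.

CPM divides each count by library size over one million.  The TPM-like
value further divides by the gene's total unambiguous intron (or exon)
length in kb, making intronic and exonic signal comparable within a sample.
DESeq2-style scale factors are deliberately not used: pull-down libraries
violate the common-scale-factor assumption (most genes depleted, few
strongly enriched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .gtf_io import strip_version

__all__ = [
    "SampleDesign",
    "assemble_count_tables",
    "compute_library_size",
    "cpm_normalize",
    "length_normalize",
    "add_condition_means",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("PD", "Input")
CATEGORIES = ("intron", "exon", "exon_strict")


@dataclass
class SampleDesign:
    """Sample sheet: sample name -> (condition, replicate label).

    Sample names must contain their condition string ("PD" or "Input"),
    honoring the naming convention the mean columns rely on.
    """

    samples: list[str] = field(default_factory=list)
    condition: dict[str, str] = field(default_factory=dict)
    replicate: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        """Build from a table with columns sample, condition, replicate."""
        design = cls()
        for _, row in df.iterrows():
            design.add(str(row["sample"]), str(row["condition"]), str(row["replicate"]))
        design.validate()
        return design

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def add(self, sample: str, condition: str, replicate: str) -> None:
        if sample in self.condition:
            raise ValueError(f"duplicate sample name {sample!r}")
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be PD or Input, got {condition!r}")
        if condition not in sample:
            raise ValueError(
                f"sample name {sample!r} must contain its condition {condition!r}"
            )
        self.samples.append(sample)
        self.condition[sample] = condition
        self.replicate[sample] = replicate

    def of_condition(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]

    def validate(self) -> None:
        for cond in CONDITIONS:
            n = len(self.of_condition(cond))
            if n < 2:
                raise ValueError(
                    f"need >=2 replicates per condition for statistics; {cond} has {n}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "condition": [self.condition[s] for s in self.samples],
                "replicate": [self.replicate[s] for s in self.samples],
            }
        )


def _clean_counts(counts: pd.Series) -> pd.Series:
    """Strip ID versions, drop special ``__``-prefixed summary rows."""
    counts = counts[~counts.index.str.startswith("__")]
    counts.index = counts.index.map(strip_version)
    return counts


def assemble_count_tables(
    per_sample_counts: Mapping[str, Mapping[str, pd.Series]],
    design: SampleDesign,
) -> dict[str, pd.DataFrame]:
    """Join per-sample count columns into one genes x samples table per category.

    ``per_sample_counts[category][sample]`` is a count Series indexed by gene
    ID.  Gene universes must match across samples within a category (they all
    come from the same annotation); a mismatch is an error naming the
    offending genes.
    """
    tables: dict[str, pd.DataFrame] = {}
    for category, by_sample in per_sample_counts.items():
        cols = {}
        universe: set[str] | None = None
        for sample in design.samples:
            col = _clean_counts(pd.Series(by_sample[sample]))
            if universe is None:
                universe = set(col.index)
            elif set(col.index) != universe:
                offenders = sorted(universe ^ set(col.index))
                raise ValueError(
                    f"category {category!r}: gene universe mismatch in sample "
                    f"{sample!r}; offending genes: {offenders[:10]}"
                )
            cols[sample] = col
        table = pd.DataFrame(cols).sort_index()
        table.index.name = "gene"
        tables[category] = table
    return tables


def compute_library_size(
    intron_raw: pd.DataFrame, exon_strict_raw: pd.DataFrame
) -> pd.Series:
    """Per-sample library size = intron-union + exon-strict column sums."""
    if list(intron_raw.columns) != list(exon_strict_raw.columns):
        raise ValueError("sample columns differ between intron and strict tables")
    lib = intron_raw.sum(axis=0) + exon_strict_raw.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    return lib.astype(float)


def cpm_normalize(table: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Counts per million of the custom library size, column-wise."""
    return table.div(library_sizes[table.columns] / 1e6, axis=1)


def add_condition_means(table: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Append row-wise ``mean_PD`` and ``mean_Input`` columns."""
    out = table.copy()
    out["mean_PD"] = table[design.of_condition("PD")].mean(axis=1)
    out["mean_Input"] = table[design.of_condition("Input")].mean(axis=1)
    return out


def length_normalize(
    cpm_tables: Mapping[str, pd.DataFrame],
    lengths: pd.DataFrame,
    design: SampleDesign,
) -> dict[str, pd.DataFrame]:
    """CPM -> TPM-like values per kb of unambiguous intron/exon length.

    Intron CPM is divided by ``in_length``/1000, exon CPM by
    ``ex_length``/1000.  Single-exon genes (``in_length`` 0) are removed
    first; genes missing from the length table are dropped with a warning
    (inner join).  The strictly exonic category exists only for the library
    size and is not length-normalized.  Per-condition mean columns are
    appended.
    """
    lengths = lengths.copy()
    lengths.index = lengths.index.map(strip_version)
    lengths = lengths[lengths["in_length"] != 0]  # removing single exon genes
    out: dict[str, pd.DataFrame] = {}
    for category, length_col in (("intron", "in_length"), ("exon", "ex_length")):
        cpm = cpm_tables[category]
        shared = cpm.index.intersection(lengths.index)
        dropped = len(cpm.index) - len(shared)
        if dropped:
            logger.warning(
                "%s: dropping %d gene(s) absent from the length table or single-exon",
                category,
                dropped,
            )
        tpm = cpm.loc[shared].div(lengths.loc[shared, length_col], axis=0) * 1000
        out[category] = add_condition_means(tpm, design)
    return out
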