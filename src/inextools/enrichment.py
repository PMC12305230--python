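"""Pull-down enrichment calling on length-normalized tables.

RBP targets are genes whose RNA is more abundant in the pull-down (PD)
fraction than in total lysate (Input).  The procedure: filter out lowly
expressed genes (mean PD signal below the overall intron-table PD mean,
which would only contribute log-transform noise), take natural logs, run a
per-gene two-sample test of PD vs Input replicates (Welch t-test by
default, since log-normalized RNA-seq abundances are approximately normal
after the log; Mann-Whitney U as the distribution-free alternative),
Benjamini-Hochberg-adjust across all genes of the table, and call a gene
enriched when p_adj <= alpha and logFC = mean_PD - mean_Input > 0.  The
final target list is the union of the genes enriched in the intronic and
in the exonic table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import SampleDesign

__all__ = [
    "EnrichmentResult",
    "compute_cutoff",
    "apply_cutoff",
    "log_transform",
    "test_per_gene",
    "bh_adjust",
    "classify_enriched",
    "enriched_union",
    "run_enrichment",
]

logger = logging.getLogger(__name__)

TEST_METHODS = ("welch", "student", "mannwhitney")


@dataclass
class EnrichmentResult:
    """Per-category test table plus the combined enriched gene set."""

    tables: dict[str, pd.DataFrame]
    enriched_genes: set[str]


def compute_cutoff(intron_tpm: pd.DataFrame) -> float:
    """Overall mean of the intron table's per-gene mean_PD column.

    This single intron-derived value is the expression cutoff for *both*
    categories: intronic signal is the scarcer of the two, and applying its
    mean to the exonic table keeps the two filtered universes comparable.
    """
    if intron_tpm.empty:
        raise ValueError("cannot compute a cutoff from an empty table")
    return float(intron_tpm["mean_PD"].mean())


def apply_cutoff(
    tables: dict[str, pd.DataFrame], cutoff: float
) -> dict[str, pd.DataFrame]:
    """Keep rows with mean_PD strictly above the cutoff, per category."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return {cat: df[df["mean_PD"] > cutoff] for cat, df in tables.items()}


def log_transform(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Natural log of every value; rows with any non-finite entry dropped.

    No pseudocount: genes with zero signal in any replicate are not of
    interest here and leave via the finite filter.
    """
    out = {}
    for cat, df in tables.items():
        with np.errstate(divide="ignore"):
            logged = np.log(df)
        out[cat] = logged[np.isfinite(logged).all(axis=1)]
    return out


def _welch_or_student(pd_vals, input_vals, equal_var: bool) -> float:
    if np.ptp(pd_vals) == 0 and np.ptp(input_vals) == 0:
        # degenerate: constant data in both groups; the test statistic is
        # undefined, but one pathological gene must not abort the run
        warnings.warn("constant data in both groups; reporting p=1.0")
        return 1.0
    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(pd_vals, input_vals, equal_var=equal_var)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def test_per_gene(
    table: pd.DataFrame, design: SampleDesign, method: str = "welch"
) -> pd.Series:
    """Two-sided per-gene test of PD vs Input replicate values.

    Each gene gets its own p-value; no pooling across genes.  ``welch`` is
    the unequal-variance t-test (default), ``student`` the pooled-variance
    variant, ``mannwhitney`` the rank-based alternative.
    """
    if method not in TEST_METHODS:
        raise ValueError(f"unknown test method {method!r}")
    pd_cols = design.of_condition("PD")
    in_cols = design.of_condition("Input")
    pvals = {}
    for gene, row in table.iterrows():
        a = row[pd_cols].to_numpy(dtype=float)
        b = row[in_cols].to_numpy(dtype=float)
        if method == "mannwhitney":
            pvals[gene] = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        else:
            pvals[gene] = _welch_or_student(a, b, equal_var=(method == "student"))
    return pd.Series(pvals, name="p_val", dtype=float)


def bh_adjust(p_values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment across all tests combined."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        adj = arr
    else:
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name="p_adj")
    return adj


def classify_enriched(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Add logFC and the enriched call: p_adj <= alpha and logFC > 0."""
    out = table.copy()
    out["logFC"] = out["mean_PD"] - out["mean_Input"]
    out["enriched"] = (out["p_adj"] <= alpha) & (out["logFC"] > 0)
    return out


def enriched_union(*tables: pd.DataFrame) -> set[str]:
    """Union of the enriched gene sets over the given category tables."""
    genes: set[str] = set()
    for df in tables:
        genes.update(df.index[df["enriched"]])
    return genes


def run_enrichment(
    tpm_tables: dict[str, pd.DataFrame],
    design: SampleDesign,
    *,
    alpha: float = 0.05,
    method: str = "welch",
) -> tuple[EnrichmentResult, dict[str, pd.DataFrame]]:
    """Cutoff -> log -> test -> BH -> classify; returns result + cutoff tables.

    The post-cutoff (pre-log) TPM tables are returned alongside because the
    InEx stage consumes them.
    """
    cutoff = compute_cutoff(tpm_tables["intron"])
    cut = apply_cutoff(tpm_tables, cutoff)
    logged = log_transform(cut)
    out_tables: dict[str, pd.DataFrame] = {}
    for cat, df in logged.items():
        if df.empty:
            logger.warning("category %s: no genes survive cutoff/log filtering", cat)
            empty = df.copy()
            for col in ("p_val", "p_adj", "logFC"):
                empty[col] = pd.Series(dtype=float)
            empty["enriched"] = pd.Series(dtype=bool)
            out_tables[cat] = empty
            continue
        df = df.copy()
        df["p_val"] = test_per_gene(df, design, method=method)
        df["p_adj"] = bh_adjust(df["p_val"])
        out_tables[cat] = classify_enriched(df, alpha=alpha)
    genes = enriched_union(*out_tables.values())
    if not genes:
        logger.warning("no enriched genes found; InEx stage will be skipped")
    return EnrichmentResult(tables=out_tables, enriched_genes=genes), cut
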