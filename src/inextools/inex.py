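"""The InEx ratio: per-gene intronic over exonic length-normalized signal.

For a gene whose transcript pool is a mix of unspliced pre-mRNA and spliced
mRNA, fragment density over introns tracks pre-mRNA abundance while density
over exons tracks total (pre-mRNA + mRNA) abundance.  The ratio of
length-normalized intronic to exonic signal, InEx = TPM_intron / TPM_exon,
therefore estimates the unspliced proportion of the pool.  Comparing InEx
of pull-down-enriched genes between PD and Input reveals whether the RBP
preferentially binds pre-mRNA (PD InEx above Input InEx) or mature mRNA.

InEx can exceed 1 — uneven coverage, annotation inaccuracy, or genuinely
pulled-down spliced-out introns; values are reported unclipped with a flag,
so the ratio is a comparative readout, not an absolute quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import SampleDesign

__all__ = [
    "ConditionComparison",
    "compute_inex",
    "compare_conditions",
    "summarize_inex",
]

logger = logging.getLogger(__name__)


@dataclass
class ConditionComparison:
    """PD-vs-Input test on per-gene mean InEx."""

    statistic: float
    p_value: float
    direction: int  # sign of mean(PD InEx) - mean(Input InEx)
    n_genes: int
    test: str  # "paired-t" or "welch-t"


def compute_inex(
    intron_tpm_cut: pd.DataFrame,
    exon_tpm_cut: pd.DataFrame,
    enriched_genes: set[str],
    design: SampleDesign,
) -> pd.DataFrame:
    """Per enriched gene, per replicate: InEx = TPM_intron / TPM_exon.

    Only genes present in *both* post-cutoff tables are kept (inner merge);
    an enriched gene surviving the cutoff in one category only is excluded
    with a logged note.  Output has one row per (gene, condition) with
    ``InEx_<replicate>`` columns, a row-wise ``mean_InEx``, and an
    ``above_one`` flag marking genes whose mean InEx exceeds 1 in that
    condition.
    """
    shared = intron_tpm_cut.index.intersection(exon_tpm_cut.index)
    genes = sorted(set(enriched_genes) & set(shared))
    skipped = set(enriched_genes) - set(shared)
    if skipped:
        logger.info(
            "%d enriched gene(s) absent from one table after cutoff, excluded",
            len(skipped),
        )
    rows = []
    for gene in genes:
        for condition in ("PD", "Input"):
            row: dict[str, object] = {"gene": gene, "condition": condition}
            values = []
            degenerate = False
            for sample in design.of_condition(condition):
                tpm_in = float(intron_tpm_cut.loc[gene, sample])
                tpm_ex = float(exon_tpm_cut.loc[gene, sample])
                if tpm_ex == 0:
                    degenerate = True
                    break
                ratio = tpm_in / tpm_ex
                row[f"InEx_{design.replicate[sample]}"] = ratio
                values.append(ratio)
            if degenerate:
                logger.warning("gene %s has zero exonic TPM; excluded from InEx", gene)
                rows = [r for r in rows if r["gene"] != gene]
                break
            row["mean_InEx"] = float(np.mean(values))
            row["above_one"] = row["mean_InEx"] > 1
            rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.set_index(["gene", "condition"])
    return table


def compare_conditions(inex: pd.DataFrame, paired: bool = True) -> ConditionComparison:
    """Two-sided t-test on per-gene mean InEx, PD vs Input.

    Paired by default — the gene sets of the two conditions are identical,
    so each gene is its own control; an unpaired Welch variant is available.
    A positive direction at significance reads "the pull-down is enriched
    for unspliced RNA", i.e. the RBP prefers pre-mRNA.
    """
    if inex.empty:
        raise ValueError("empty InEx table")
    wide = inex["mean_InEx"].unstack("condition").dropna()
    if len(wide) < 2:
        raise ValueError(f"need >=2 genes with both conditions, got {len(wide)}")
    pd_vals = wide["PD"].to_numpy(dtype=float)
    in_vals = wide["Input"].to_numpy(dtype=float)
    if paired:
        if np.allclose(pd_vals, in_vals):
            res_stat, res_p, name = 0.0, 1.0, "paired-t"
        else:
            res = stats.ttest_rel(pd_vals, in_vals)
            res_stat, res_p, name = float(res.statistic), float(res.pvalue), "paired-t"
    else:
        res = stats.ttest_ind(pd_vals, in_vals, equal_var=False)
        res_stat, res_p, name = float(res.statistic), float(res.pvalue), "welch-t"
    if np.isnan(res_p):
        res_stat, res_p = 0.0, 1.0
    diff = float(pd_vals.mean() - in_vals.mean())
    return ConditionComparison(
        statistic=res_stat,
        p_value=res_p,
        direction=int(np.sign(diff)),
        n_genes=len(wide),
        test=name,
    )


def summarize_inex(inex: pd.DataFrame) -> pd.DataFrame:
    """Quartiles, mean and n of mean InEx per condition (plot-ready)."""
    if inex.empty:
        raise ValueError("empty InEx table")
    rows = {}
    for condition, grp in inex.groupby(level="condition"):
        vals = grp["mean_InEx"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"no genes for condition {condition}")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows[condition] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
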