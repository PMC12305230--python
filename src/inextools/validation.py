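"""Calibration experiments on synthetic data with known ground truth.

These are the package's self-checks, runnable by users: does the mean InEx
recover a known unspliced fraction, is the enrichment test's false-positive
rate controlled on null data, does an 8-fold pull-down enrichment get
called, and does a pre-mRNA-binding protein produce the expected PD > Input
InEx shift end-to-end?
"""

from __future__ import annotations

import logging
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
import pandas as pd

from . import annotation as ann
from . import counting, enrichment, gtf_io, quantify, simulate
from .inex import ConditionComparison, compare_conditions, compute_inex
from .pipeline import RunConfig, run_all

__all__ = [
    "mixture_mean_inex",
    "null_enrichment_rates",
    "enrichment_recovery",
    "pulldown_shift_experiment",
]

logger = logging.getLogger(__name__)


def _quantify_dir(sam_paths: dict[str, Path], records, strandedness="reverse"):
    """GTF records + SAMs -> per-sample TPM tables (no condition means)."""
    pool = list(ann.filter_protein_coding_exons(records))
    per_exon = {
        s: counting.count_fragments(
            p, pool, mode="union", key="exon_id", strandedness=strandedness
        ).to_dict()
        for s, p in sam_paths.items()
    }
    annotation, lengths = ann.build_reference(records, per_exon)
    exon_f, intron_f = annotation.by_type("exon"), annotation.by_type("intron")
    raw = {"intron": {}, "exon": {}, "exon_strict": {}}
    for s, p in sam_paths.items():
        raw["intron"][s] = counting.count_fragments(
            p, intron_f, mode="union", strandedness=strandedness
        )
        raw["exon"][s] = counting.count_fragments(
            p, exon_f, mode="union", strandedness=strandedness
        )
        raw["exon_strict"][s] = counting.count_fragments(
            p, exon_f, mode="intersection_strict", strandedness=strandedness
        )
    tables = {
        c: pd.DataFrame({s: col for s, col in by_sample.items()}).sort_index()
        for c, by_sample in raw.items()
    }
    for c in tables:
        tables[c].index = tables[c].index.map(gtf_io.strip_version)
    lib = quantify.compute_library_size(tables["intron"], tables["exon_strict"])
    cpm = {c: quantify.cpm_normalize(t, lib) for c, t in tables.items()}
    lengths = lengths.copy()
    lengths.index = lengths.index.map(gtf_io.strip_version)
    lengths = lengths[lengths["in_length"] != 0]
    shared = cpm["intron"].index.intersection(lengths.index)
    tpm = {
        "intron": cpm["intron"].loc[shared].div(lengths.loc[shared, "in_length"], axis=0) * 1000,
        "exon": cpm["exon"].loc[shared].div(lengths.loc[shared, "ex_length"], axis=0) * 1000,
    }
    return tpm


def mixture_mean_inex(
    phi: float,
    *,
    n_fragments: int = 50_000,
    n_genes: int = 20,
    n_samples: int = 2,
    seed: int = 0,
) -> float:
    """Mean per-gene InEx when every gene's unspliced molar fraction is phi.

    Simulates ``n_samples`` libraries of ``n_fragments`` fragments from a
    genome without pull-down structure, runs annotation building, counting
    and normalization, and averages TPM_intron/TPM_exon over genes and
    samples.  Converges to phi up to exon-intron boundary-fragment effects.
    """
    truth = simulate.generate_genome(
        n_genes,
        seed=seed,
        target_fraction=0.0,
        single_exon_fraction=0.0,
        noncoding_fraction=0.0,
    )
    records = simulate.genome_records(truth)
    with TemporaryDirectory() as tmp:
        sams = {}
        for i in range(n_samples):
            p = Path(tmp) / f"s{i}.sam"
            simulate.simulate_fragments(
                truth, "Input", n_fragments, p, seed=seed + 7919 * (i + 1),
                phi_override=phi,
            )
            sams[f"s{i}"] = p
        tpm = _quantify_dir(sams, records)
    ratio = tpm["intron"] / tpm["exon"]
    ratio = ratio.replace([np.inf, -np.inf], np.nan).dropna(how="all")
    return float(ratio.mean(axis=1).mean())


def _lognormal_tpm_tables(
    rng: np.random.Generator,
    n_genes: int,
    samples: list[str],
    enriched_factor: float = 1.0,
    n_enriched: int = 0,
    sigma_gene: float = 1.0,
    sigma_rep: float = 0.25,
) -> dict[str, pd.DataFrame]:
    """Log-normal abundance tables at the TPM stage, per category."""
    factors = np.ones(n_genes)
    factors[:n_enriched] = enriched_factor
    tables = {}
    for cat in ("intron", "exon"):
        base = rng.lognormal(mean=2.0, sigma=sigma_gene, size=n_genes)
        vals = {}
        for s in samples:
            noise = rng.lognormal(mean=0.0, sigma=sigma_rep, size=n_genes)
            vals[s] = base * noise * (factors if s.startswith("PD") else 1.0)
        df = pd.DataFrame(vals, index=[f"G{i}" for i in range(n_genes)])
        pd_cols = [s for s in samples if s.startswith("PD")]
        in_cols = [s for s in samples if s.startswith("Input")]
        df["mean_PD"] = df[pd_cols].mean(axis=1)
        df["mean_Input"] = df[in_cols].mean(axis=1)
        tables[cat] = df
    return tables


def _design_3v3() -> quantify.SampleDesign:
    rows = [
        {"sample": f"{c}_{r}", "condition": c, "replicate": str(r)}
        for c in ("PD", "Input")
        for r in (1, 2, 3)
    ]
    return quantify.SampleDesign.from_frame(pd.DataFrame(rows))


def null_enrichment_rates(
    n_genes: int = 2000, seed: int = 0
) -> tuple[float, int]:
    """(fraction of raw p <= 0.05, size of BH-0.05 enriched set) under the null.

    PD and Input replicates are drawn from one log-normal distribution per
    gene (3 vs 3), so every positive is false.  The raw rate is the test's
    own calibration, measured per gene on all genes of both categories
    (the expression cutoff is a filtering step, not part of the test);
    the enriched-set size measures the full procedure including cutoff
    and BH control.
    """
    rng = np.random.default_rng(seed)
    design = _design_3v3()
    tables = _lognormal_tpm_tables(rng, n_genes, design.samples)
    logged = enrichment.log_transform(tables)
    pvals = pd.concat(
        [enrichment.test_per_gene(df, design) for df in logged.values()]
    )
    result, _ = enrichment.run_enrichment(tables, design)
    return float((pvals <= 0.05).mean()), len(result.enriched_genes)


def enrichment_recovery(
    n_runs: int = 20,
    *,
    n_genes: int = 500,
    n_enriched: int = 25,
    factor: float = 8.0,
    seed: int = 0,
) -> float:
    """Fraction of truly PD-enriched genes found in the enriched union.

    ``n_runs`` independent simulations with ``n_enriched`` genes at a
    ``factor``-fold PD abundance increase; returns the overall recovery
    fraction over all runs and genes.
    """
    design = _design_3v3()
    truly = {f"G{i}" for i in range(n_enriched)}
    recovered = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        tables = _lognormal_tpm_tables(
            rng, n_genes, design.samples, enriched_factor=factor,
            n_enriched=n_enriched,
        )
        result, _ = enrichment.run_enrichment(tables, design)
        recovered += len(truly & result.enriched_genes)
    return recovered / (n_runs * n_enriched)


def pulldown_shift_experiment(
    *,
    n_genes: int = 50,
    n_fragments: int = 20_000,
    replicates: int = 3,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[ConditionComparison, dict]:
    """Full pipeline on a pre-mRNA-binding pull-down simulation.

    Target genes carry an 8-fold PD abundance enrichment and a raised
    unspliced fraction in PD (0.4 vs 0.1 in Input).  Returns the PD-vs-Input
    InEx comparison and the run manifest.  The expected outcome is a
    significant positive shift: the simulated protein binds pre-mRNA.
    """
    import json

    def _run(tmp: Path):
        truth = simulate.generate_genome(n_genes, seed=seed)
        gtf = tmp / "genome.gtf"
        gtf_io.write_gtf(simulate.genome_records(truth), gtf)
        rows = []
        for cond in ("Input", "PD"):
            for rep in range(1, replicates + 1):
                sample = f"{cond}_{rep}"
                p = tmp / f"{sample}.sam"
                simulate.simulate_fragments(
                    truth, cond, n_fragments, p, seed=seed + 104729 * (len(rows) + 1)
                )
                rows.append(
                    {"sample": sample, "condition": cond, "replicate": str(rep),
                     "path": str(p)}
                )
        design = tmp / "design.tsv"
        pd.DataFrame(rows).to_csv(design, sep="\t", index=False)
        config = RunConfig(
            gtf=str(gtf), design=str(design), out_dir=str(tmp / "run"), seed=seed
        )
        out = run_all(config)
        manifest = json.loads((out / "manifest.json").read_text())
        comparison_raw = json.loads((out / "comparison.json").read_text())
        return ConditionComparison(**comparison_raw), manifest

    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        return _run(Path(out_dir))
    with TemporaryDirectory() as tmp:
        return _run(Path(tmp))
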