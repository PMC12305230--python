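"""End-to-end orchestration: annotation -> counting -> normalization ->
enrichment -> InEx, with a manifest of per-stage row counts.

Thresholds and modes are configuration with the method's defaults
(reverse-stranded counting, alpha 0.05, cutoff = overall intron PD mean),
never hard-coded in the stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import counting, enrichment, gtf_io, quantify
from .inex import compare_conditions, compute_inex, summarize_inex

__all__ = ["RunConfig", "run_all", "check_strandedness_diagnostic"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gtf: str
    design: str  # TSV: sample, condition, replicate, path
    out_dir: str
    strandedness: str = "reverse"
    alpha: float = 0.05
    test: str = "welch"
    paired_comparison: bool = True
    protein_coding_filter: bool = True
    keep_intermediates: bool = False
    strict_checks: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> pd.DataFrame:
        if self.strandedness not in counting.STRANDEDNESS_MODES:
            raise ValueError(f"invalid strandedness {self.strandedness!r}")
        for p in (self.gtf, self.design):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        sheet = pd.read_csv(self.design, sep="\t")
        missing = [p for p in sheet["path"] if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"alignment files missing: {missing}")
        return sheet

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute every stage in order; returns the run directory.

    Writes annotations.gtf, lengths.csv, per-sample count TSVs, TPM tables,
    enrichment tables, inex.tsv, comparison.json and a manifest.json with
    the per-stage counts worth eyeballing after a run (annotation counts
    before/after subtraction and collapsing, table row counts).
    """
    sheet = config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = quantify.SampleDesign.from_frame(sheet)
    paths = dict(zip(sheet["sample"].astype(str), sheet["path"]))
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}

    # --- reference building -------------------------------------------------
    records = list(gtf_io.parse_gtf(config.gtf))
    if config.protein_coding_filter:
        exon_pool = list(ann.filter_protein_coding_exons(records))
    else:
        exon_pool = [r for r in records if r.feature_type == "exon"]
    if not exon_pool:
        raise ValueError(f"stage build-annotation: no usable exons in {config.gtf}")
    per_exon_counts = {
        sample: counting.count_fragments(
            paths[sample],
            exon_pool,
            mode="union",
            key="exon_id",
            strandedness=config.strandedness,
        ).to_dict()
        for sample in design.samples
    }
    annotation, lengths = ann.build_reference(
        records,
        per_exon_counts,
        protein_coding_filter=config.protein_coding_filter,
        strict_checks=config.strict_checks,
    )
    gtf_io.write_gtf(annotation, out / "annotations.gtf")
    lengths.to_csv(out / "lengths.csv")
    manifest["stages"]["annotation"] = {
        "features": len(annotation),
        "genes": int(lengths.shape[0]),
    }

    # --- fragment counting --------------------------------------------------
    exon_feats = annotation.by_type("exon")
    intron_feats = annotation.by_type("intron")
    if not intron_feats:
        raise ValueError("stage count: annotation has no intron features")
    count_plan = {
        "intron": (intron_feats, "union"),
        "exon": (exon_feats, "union"),
        "exon_strict": (exon_feats, "intersection_strict"),
    }
    raw_counts: dict[str, dict[str, pd.Series]] = {c: {} for c in count_plan}
    for sample, (category, (feats, mode)) in itertools.product(
        design.samples, count_plan.items()
    ):
        col = counting.count_fragments(
            paths[sample], feats, mode=mode, key="gene_id",
            strandedness=config.strandedness,
        )
        raw_counts[category][sample] = col
        if config.keep_intermediates:
            col.to_csv(out / f"counts_{sample}.{category}.tsv", sep="\t", header=False)

    # --- normalization ------------------------------------------------------
    tables = quantify.assemble_count_tables(raw_counts, design)
    lib = quantify.compute_library_size(tables["intron"], tables["exon_strict"])
    lib.to_frame("library_size").to_csv(out / "libsize.tsv", sep="\t")
    cpm = {c: quantify.cpm_normalize(t, lib) for c, t in tables.items()}
    tpm = quantify.length_normalize(cpm, lengths, design)
    for cat in ("intron", "exon"):
        tpm[cat].to_csv(out / f"{cat}.tpm.tsv", sep="\t")
    manifest["stages"]["quantify"] = {c: int(t.shape[0]) for c, t in tpm.items()}

    # --- enrichment ---------------------------------------------------------
    result, cut = enrichment.run_enrichment(
        tpm, design, alpha=config.alpha, method=config.test
    )
    for cat, df in result.tables.items():
        df.to_csv(out / f"enrichment_{cat}.tsv", sep="\t")
    pd.Series(sorted(result.enriched_genes), name="gene").to_csv(
        out / "enriched_genes.csv", index=False
    )
    manifest["stages"]["enrichment"] = {
        cat: int(df["enriched"].sum()) for cat, df in result.tables.items()
    }
    manifest["stages"]["enriched_union"] = len(result.enriched_genes)

    # --- InEx ---------------------------------------------------------------
    if result.enriched_genes:
        inex_table = compute_inex(
            cut["intron"], cut["exon"], result.enriched_genes, design
        )
        inex_table.to_csv(out / "inex.tsv", sep="\t")
        comparison = compare_conditions(inex_table, paired=config.paired_comparison)
        with open(out / "comparison.json", "w") as fh:
            json.dump(dataclasses.asdict(comparison), fh, indent=2)
        summarize_inex(inex_table).to_csv(out / "inex_summary.tsv", sep="\t")
        manifest["stages"]["inex"] = {
            "genes": comparison.n_genes,
            "p_value": comparison.p_value,
            "direction": comparison.direction,
        }
    else:
        logger.warning("no enriched genes; skipping InEx stage")
        manifest["stages"]["inex"] = None

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def check_strandedness_diagnostic(
    alignment_path: str | Path,
    annotation: ann.AnnotationSet,
    n_fragments: int = 10_000,
) -> dict:
    """Estimate which strandedness mode fits the library.

    Counts the fraction of (up to) ``n_fragments`` fragments assigned to any
    feature under reverse vs forward mode and recommends the mode with the
    higher assignment rate; near-equal rates mean the library looks
    unstranded and no recommendation is made.
    """
    index = counting.FeatureIndex(list(annotation), key="gene_id")
    rates = {}
    total = 0
    for mode in ("reverse", "forward"):
        assigned = total = 0
        for frag in itertools.islice(
            counting.assemble_fragments(alignment_path, strandedness=mode),
            n_fragments,
        ):
            total += 1
            if index.overlapping(frag):
                assigned += 1
        if total == 0:
            raise ValueError("no mapped fragments in input")
        rates[mode] = assigned / total
    if total < 1000:
        logger.warning("only %d fragments available; diagnostic is noisy", total)
    hi, lo = max(rates.values()), min(rates.values())
    if hi > 0 and (hi - lo) / hi > 0.2:
        recommendation = max(rates, key=rates.get)
    else:
        recommendation = None  # looks unstranded
    return {
        "assigned_fraction": rates,
        "n_fragments": total,
        "recommendation": recommendation,
    }
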