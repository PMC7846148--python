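"""End-to-end orchestration: QC -> normalize -> fit -> classify -> report.

``run_full_analysis`` wires the stages together from a single RunConfig:
contamination filtering, library collapsing, TMM normalization, the
low-expression filter, the pooled regime x temperature NB GLM, the
three-step plasticity analysis with the false-positive guard and the
direction/concordance tests, replicate-specific classification, and
(optionally) gene-set enrichment.  All tables are written as TSV, the run
summary as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_qc import (
    CountMatrix,
    collapse_libraries,
    contamination_filter,
    downsample_counts,
    read_counts,
    read_marker_list,
)
from .nbglm import GLMAnalysis, main_design
from .normalization import compute_tmm_factors, filter_low_expression
from .plasticity import (
    PlasticityAnalysis,
    direction_bias_test,
    restrict_to_ancestrally_plastic,
    sign_concordance_test,
)
from .replicates import consistency_metrics, per_replicate_classification
from .enrichment import GeneSetCollection, bootstrap_equalized_enrichment, hypergeometric_enrichment

log = logging.getLogger("normevol")


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for a full pipeline run."""

    counts_path: str
    samplesheet_path: str
    outdir: str
    markers_path: str | None = None
    gmt_path: str | None = None
    cpm_threshold: float = 1.0
    de_fdr: float = 0.05
    interaction_fdr: float = 0.10
    contamination_threshold: float = 8.0
    focal_regime: str = "hot"
    downsample_depth: int | None = None
    dispersion_shrink: str = "trend"
    run_replicates: bool = True
    run_enrichment: bool = True
    enrichment_n_iter: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_fdr", "interaction_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be nonnegative")
        for p in (self.counts_path, self.samplesheet_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline and return the summary dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "cpm": config.cpm_threshold,
            "de_fdr": config.de_fdr,
            "interaction_fdr": config.interaction_fdr,
            "contamination": config.contamination_threshold,
        },
    }

    m = read_counts(config.counts_path, config.samplesheet_path)
    summary["n_genes_input"] = m.n_genes
    summary["n_libraries_input"] = m.n_samples
    log.info("read %d genes x %d libraries", m.n_genes, m.n_samples)

    if config.markers_path:
        markers = read_marker_list(config.markers_path)
        m, flagged = contamination_filter(
            m, markers, threshold=config.contamination_threshold
        )
        summary["contaminated_libraries"] = flagged
        pd.Series(flagged, name="library").to_csv(
            out / "flagged_libraries.tsv", sep="\t", index=False
        )
        log.info("contamination filter removed %d libraries", len(flagged))

    m = collapse_libraries(m)
    summary["n_samples_collapsed"] = m.n_samples

    if config.downsample_depth:
        m = downsample_counts(m, config.downsample_depth, seed=config.seed)

    norm = compute_tmm_factors(m)
    m = filter_low_expression(m, norm, threshold=config.cpm_threshold)
    norm = compute_tmm_factors(m)
    norm.write(out / "tmm_factors.tsv")
    summary["n_genes_retained"] = m.n_genes
    log.info("retained %d genes above %.2g CPM", m.n_genes, config.cpm_threshold)

    design = main_design(m.samples)
    analysis = GLMAnalysis(m, design, norm, shrink=config.dispersion_shrink)
    pa = PlasticityAnalysis(analysis)

    # step (a): within-group plasticity
    plastic = {}
    for group in design.groups:
        rn = pa.call_plasticity(group, fdr=config.de_fdr)
        rn.to_csv(out / f"reaction_norms_{group}.tsv", sep="\t", index_label="gene_id")
        plastic[group] = int(rn["plastic"].sum())
    summary["n_plastic"] = plastic
    summary["pct_plastic"] = {
        g: round(100.0 * n / m.n_genes, 1) for g, n in plastic.items()
    }

    # step (b): evolved expression per regime and temperature
    evolved = {}
    for group in design.groups:
        if group == "ancestral":
            continue
        for temp in (15, 23):
            t = pa.call_evolved_expression(group, temp, fdr=config.de_fdr)
            t.to_csv(out / f"evolved_{group}_{temp}.tsv", sep="\t", index_label="gene_id")
            evolved[f"{group}_{temp}"] = int(t["significant"].sum())
    summary["n_evolved_de"] = evolved

    # step (c): classification, guard, direction bias, sign concordance
    focal = config.focal_regime
    table = pa.classify_reaction_norms(
        focal, de_fdr=config.de_fdr, interaction_fdr=config.interaction_fdr
    )
    table.to_csv(out / f"plasticity_classes_{focal}.tsv", sep="\t", index_label="gene_id")
    class_counts = {k: v for k, v in table.attrs.items() if k.startswith("n_")}
    summary["classification"] = class_counts
    n_inc = table.attrs["n_increased"]
    n_dec = table.attrs["n_decreased"]
    if n_inc + n_dec > 0:
        summary["direction_bias"] = direction_bias_test(n_inc, n_dec)
        sub = restrict_to_ancestrally_plastic(table)
        n_inc_p = int((sub["class"] == "INCREASED").sum())
        n_dec_p = int((sub["class"] == "DECREASED").sum())
        if n_inc_p + n_dec_p > 0:
            summary["direction_bias_ancestrally_plastic"] = direction_bias_test(
                n_inc_p, n_dec_p
            )
    sig = table[table["class"].isin(["INCREASED", "DECREASED"])]
    if len(sig):
        summary["guard"] = {
            "n_tested": int(len(sig)),
            "n_passed": int(sig["guard_pass"].sum()),
        }
    for cls in ("INCREASED", "DECREASED"):
        if (table["class"] == cls).sum() >= 2:
            try:
                summary[f"sign_concordance_{cls.lower()}"] = sign_concordance_test(
                    table, cls
                )
            except ValueError:
                pass

    # replicate-specific analysis
    if config.run_replicates:
        rc = per_replicate_classification(
            m,
            norm,
            focal_regime=focal,
            de_fdr=config.de_fdr,
            interaction_fdr=config.interaction_fdr,
            shrink=config.dispersion_shrink,
        )
        cons = consistency_metrics(rc)
        cons.pairwise_r2.to_csv(out / "replicate_pairwise_r2.tsv", sep="\t", index=False)
        cons.significance_counts.to_csv(
            out / "replicate_significance_counts.tsv", sep="\t", index_label="gene_id"
        )
        summary["replicates"] = {
            "n_significant": cons.n_significant,
            "shared_frequency": cons.shared_frequency,
            "mean_r2": cons.mean_r2,
            "skipped": rc.skipped,
        }

    # enrichment on the classified lists
    if config.run_enrichment and config.gmt_path:
        coll = GeneSetCollection.from_gmt(config.gmt_path, m.gene_ids)
        inc_genes = list(table.index[table["class"] == "INCREASED"])
        dec_genes = list(table.index[table["class"] == "DECREASED"])
        enr = {}
        for name, genes in (("increased", inc_genes), ("decreased", dec_genes)):
            if genes:
                res = hypergeometric_enrichment(genes, coll, fdr=config.de_fdr)
                res.to_csv(out / f"enrichment_{name}.tsv", sep="\t")
                enr[name] = int(res["enriched"].sum())
        summary["enrichment"] = enr
        if inc_genes and dec_genes and len(inc_genes) >= len(dec_genes):
            summary["enrichment_bootstrap"] = bootstrap_equalized_enrichment(
                inc_genes,
                dec_genes,
                coll,
                n_iter=config.enrichment_n_iter,
                fdr=config.de_fdr,
                seed=config.seed,
            )

    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("summary written to %s", out / "summary.json")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
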