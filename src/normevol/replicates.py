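"""Replicate-specific evolution and cross-replicate consistency.

Instead of pooling the five evolved replicate populations into one regime
level, the replicate model gives the selection factor six levels — the
ancestral population plus each focal-regime replicate — so each replicate
gets its own evolved-expression and interaction contrasts against the
ancestral baseline.  Consistency across replicates is summarized by (i)
the shared-significance frequency (probability that a gene significant in
one replicate is significant in another) and (ii) the mean pairwise r^2 of
reaction-norm changes, both split by direction of the plasticity change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .io_qc import CountMatrix
from .nbglm import GLMAnalysis, replicate_design
from .normalization import NormFactors
from .plasticity import PlasticityAnalysis

DIRECTIONS = ("INCREASED", "DECREASED")


@dataclass
class ReplicateClassification:
    """Per-replicate class tables plus genome-wide slope-change estimates."""

    tables: dict[str, pd.DataFrame]   # replicate level -> class table
    delta_slope: pd.DataFrame         # genes x replicate levels (log2FC units)
    skipped: list[str]


@dataclass
class ReplicateConsistency:
    significance_counts: pd.DataFrame  # genes x directions: in how many replicates
    shared_frequency: dict[str, float]  # direction -> mean P(sig in j | sig in i)
    mean_r2: dict[str, float]           # direction -> mean pairwise r^2 of delta-slope
    pairwise_r2: pd.DataFrame           # one row per (direction, pair)
    n_significant: dict[str, dict[str, int]]  # direction -> replicate -> count


def per_replicate_classification(
    m: CountMatrix,
    norm: NormFactors | None = None,
    focal_regime: str = "hot",
    de_fdr: float = 0.05,
    interaction_fdr: float = 0.10,
    shrink: str = "trend",
) -> ReplicateClassification:
    """Run the full classification once per focal-regime replicate.

    Dispersion is estimated once on the six-level design and shared across
    all replicate contrasts.  Replicates missing one of the two assay
    temperatures are skipped with a warning.
    """
    keep = m.samples["regime"].isin(["ancestral", focal_regime])
    sub = m.subset_samples(m.samples.index[keep])
    if norm is not None:
        norm = NormFactors(
            factors=norm.factors.loc[sub.samples.index],
            effective_sizes=norm.effective_sizes.loc[sub.samples.index],
        )

    # drop replicates without both temperatures
    skipped = []
    focal = sub.samples[sub.samples["regime"] == focal_regime]
    for rep, grp in focal.groupby("replicate"):
        if set(grp["assay_temperature"].astype(int)) != {15, 23}:
            skipped.append(f"{focal_regime}_rep{int(rep)}")
            warnings.warn(
                f"replicate {int(rep)} of {focal_regime} lacks a temperature; skipped"
            )
    if skipped:
        bad_reps = {int(s.rsplit("rep", 1)[1]) for s in skipped}
        drop = sub.samples.index[
            (sub.samples["regime"] == focal_regime)
            & sub.samples["replicate"].astype(int).isin(bad_reps)
        ]
        sub = sub.subset_samples([s for s in sub.samples.index if s not in set(drop)])
        if norm is not None:
            norm = NormFactors(
                factors=norm.factors.loc[sub.samples.index],
                effective_sizes=norm.effective_sizes.loc[sub.samples.index],
            )

    design = replicate_design(sub.samples, focal_regime=focal_regime)
    analysis = GLMAnalysis(sub, design, norm, shrink=shrink)
    pa = PlasticityAnalysis(analysis)
    levels = [g for g in design.groups if g != "ancestral"]
    if len(levels) < 2:
        raise ValueError("replicate analysis needs at least two usable replicates")

    tables = {}
    delta = {}
    for lv in levels:
        tables[lv] = pa.classify_reaction_norms(
            lv, de_fdr=de_fdr, interaction_fdr=interaction_fdr
        )
        delta[lv] = analysis.estimate({f"{lv}:temp23": 1.0})
    return ReplicateClassification(
        tables=tables, delta_slope=pd.DataFrame(delta), skipped=skipped
    )


def consistency_metrics(
    rc: ReplicateClassification,
    gene_universe: str = "either",
    min_genes: int = 3,
) -> ReplicateConsistency:
    """Cross-replicate consistency of plasticity-evolution calls.

    shared_frequency: over ordered replicate pairs (i, j), the fraction of
    genes called in direction d in replicate i that are also called d in j.
    mean_r2: over unordered pairs, squared Pearson correlation of the
    reaction-norm change (delta-slope) across genes called in either
    (``gene_universe="either"``, default) or both (``"both"``) members of
    the pair.  Pairs with fewer than ``min_genes`` usable genes are skipped
    (a two-point r^2 is identically 1 and carries no information).
    """
    if len(rc.tables) < 2:
        raise ValueError("need at least two replicate tables")
    levels = list(rc.tables)
    sig = {
        d: {lv: set(t.index[t["class"] == d]) for lv, t in rc.tables.items()}
        for d in DIRECTIONS
    }

    all_genes = rc.delta_slope.index
    counts = pd.DataFrame(0, index=all_genes, columns=list(DIRECTIONS))
    for d in DIRECTIONS:
        for lv in levels:
            counts.loc[list(sig[d][lv]), d] += 1

    shared = {}
    for d in DIRECTIONS:
        fracs = [
            len(sig[d][i] & sig[d][j]) / len(sig[d][i])
            for i, j in permutations(levels, 2)
            if len(sig[d][i]) > 0
        ]
        shared[d] = float(np.mean(fracs)) if fracs else np.nan

    rows = []
    for d in DIRECTIONS:
        for i, j in combinations(levels, 2):
            genes = sig[d][i] | sig[d][j] if gene_universe == "either" else sig[d][i] & sig[d][j]
            genes = sorted(genes)
            if len(genes) < min_genes:
                continue
            x = rc.delta_slope.loc[genes, i].to_numpy()
            y = rc.delta_slope.loc[genes, j].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"direction": d, "rep_i": i, "rep_j": j, "n_genes": len(genes), "r2": r * r})
    pairwise = pd.DataFrame(rows, columns=["direction", "rep_i", "rep_j", "n_genes", "r2"])
    mean_r2 = {
        d: float(pairwise.loc[pairwise["direction"] == d, "r2"].mean())
        if (pairwise["direction"] == d).any()
        else np.nan
        for d in DIRECTIONS
    }
    n_sig = {d: {lv: len(sig[d][lv]) for lv in levels} for d in DIRECTIONS}
    return ReplicateConsistency(
        significance_counts=counts,
        shared_frequency=shared,
        mean_r2=mean_r2,
        pairwise_r2=pairwise,
        n_significant=n_sig,
    )
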