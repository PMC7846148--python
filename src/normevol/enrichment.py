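"""Gene-set over-representation with bootstrap size equalization.

Over-representation of a query gene list in user-supplied GMT gene sets is
tested with the one-sided hypergeometric upper tail against the retained
genes as background, BH-adjusted across sets.  Because a longer query list
mechanically yields more enriched sets, two lists of different length are
compared by repeatedly subsampling the longer list down to the size of the
shorter and counting enriched sets per subsample; the shorter list's count
is then placed within that distribution (empirical rank p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .nbglm import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, frozenset]
    background: frozenset

    @classmethod
    def from_gmt(cls, path, background) -> "GeneSetCollection":
        return cls.from_sets(read_gmt(path), background)

    @classmethod
    def from_sets(cls, sets: dict, background) -> "GeneSetCollection":
        bg = frozenset(background)
        restricted = {}
        for name, members in sets.items():
            inside = frozenset(members) & bg
            if inside:
                restricted[name] = inside
            else:
                warnings.warn(f"gene set {name!r} has no background members; dropped")
        return cls(sets=restricted, background=bg)


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file: per line, set name, description, member ids (tabs)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def hypergeometric_enrichment(
    query_genes,
    collection: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each set against the query.

    With background size M, set size n, query size N and overlap k the
    p-value is P(X >= k), X ~ Hypergeom(M, n, N).  Returns one row per set
    (overlap, set_size, p, q, enriched), sorted by p.
    """
    query = frozenset(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    stray = query - collection.background
    if stray:
        raise ValueError(
            f"query genes outside the background: {sorted(stray)[:5]}"
        )
    M, N = len(collection.background), len(query)
    rows = []
    for name, members in collection.sets.items():
        n = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append({"set": name, "overlap": k, "set_size": n, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["enriched"] = out["q"] < fdr
        out = out.sort_values("p")
    return out


def bootstrap_equalized_enrichment(
    list_a,
    list_b,
    collection: GeneSetCollection,
    n_iter: int = 20,
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Compare enrichment of two lists after equalizing their sizes.

    ``list_a`` (the longer) is subsampled without replacement to
    ``len(list_b)`` in each of ``n_iter`` iterations; the number of
    enriched sets (q < fdr) is recorded per iteration and compared with
    the count for ``list_b``.  The comparison p-value is the empirical
    rank of b's count within the subsample distribution,
    (1 + #{iterations with count <= b}) / (n_iter + 1) — small when the
    equally-sized subsamples of a are consistently more enriched than b.
    """
    list_a = list(dict.fromkeys(list_a))
    list_b = list(dict.fromkeys(list_b))
    if len(list_b) == 0:
        raise ValueError("list_b is empty")
    if len(list_a) < len(list_b):
        raise ValueError("list_a must be at least as long as list_b")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_iter):
        sub = rng.choice(list_a, size=len(list_b), replace=False)
        res = hypergeometric_enrichment(sub, collection, fdr=fdr)
        counts.append(int(res["enriched"].sum()) if len(res) else 0)
    res_b = hypergeometric_enrichment(list_b, collection, fdr=fdr)
    count_b = int(res_b["enriched"].sum()) if len(res_b) else 0
    counts = np.asarray(counts)
    p = (1 + int(np.sum(counts <= count_b))) / (n_iter + 1)
    return {
        "iteration_counts": counts.tolist(),
        "mean_count_a": float(counts.mean()),
        "count_b": count_b,
        "comparison_p": float(p),
        "n_iter": int(n_iter),
        "subsample_size": len(list_b),
    }
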