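"""Between-sample normalization: TMM scaling factors, CPM, expression filter.

TMM (trimmed mean of M-values) estimates, for each library, a scaling
factor relative to a reference library from a weighted mean of per-gene
log2 expression ratios (M-values) after trimming the most extreme M- and
A-values.  Under the assumption that most genes are not differentially
expressed, the factor absorbs composition bias that raw library-size
scaling cannot.  Effective library size = raw total x factor; CPM are
computed against effective sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import CountMatrix


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and effective library sizes."""

    factors: pd.Series          # dimensionless, geometric mean 1
    effective_sizes: pd.Series  # raw total x factor

    def write(self, path) -> None:
        pd.DataFrame(
            {"factor": self.factors, "effective_size": self.effective_sizes}
        ).to_csv(path, sep="\t", index_label="sample_id")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2^f).

    M = log2((obs/n_obs)/(ref/n_ref)); A = 0.5*log2(obs*ref/(n_obs*n_ref));
    genes with zero in either library are excluded; the upper/lower
    ``logratio_trim`` tail of M and ``abs_trim`` tail of A are trimmed and
    the remaining M averaged with inverse delta-method variance weights.
    """
    ok = (obs > 0) & (ref > 0)
    obs = obs[ok].astype(float)
    ref = ref[ok].astype(float)
    if obs.size == 0:
        raise ValueError("no co-expressed genes between sample and reference")
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M per gene
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 1.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks are 1-based; keep strictly inside both trim windows
    rank_m = pd.Series(m).rank(method="first").to_numpy()
    rank_a = pd.Series(a).rank(method="first").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def choose_reference(counts: pd.DataFrame) -> str:
    """Reference = sample whose 75th-percentile CPM is closest to the mean
    of those percentiles across samples (standard TMM convention)."""
    totals = counts.sum(axis=0).to_numpy().astype(float)
    q = np.array(
        [
            np.quantile(counts.iloc[:, j].to_numpy() / totals[j], 0.75)
            for j in range(counts.shape[1])
        ]
    )
    return counts.columns[int(np.argmin(np.abs(q - q.mean())))]


def compute_tmm_factors(
    m: CountMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """TMM scaling factors for every sample, rescaled to geometric mean 1."""
    if m.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    totals = m.library_sizes.astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    ref_id = reference if reference is not None else choose_reference(m.counts)
    ref = m.counts[ref_id].to_numpy()
    n_ref = float(totals[ref_id])
    factors = {}
    for sid in m.counts.columns:
        if sid == ref_id:
            factors[sid] = 1.0
        else:
            factors[sid] = _tmm_pair(
                m.counts[sid].to_numpy(), ref, float(totals[sid]), n_ref,
                logratio_trim, abs_trim,
            )
    f = pd.Series(factors)[m.counts.columns]
    f = f / np.exp(np.mean(np.log(f)))  # geometric mean 1
    return NormFactors(factors=f, effective_sizes=totals * f)


def cpm(
    m: CountMatrix,
    f: NormFactors | None = None,
    log_scale: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million against effective library sizes.

    Linear scale: count * 1e6 / effective_size.  Log scale:
    log2((count + prior) / (effective_size + 2*prior) * 1e6), the usual
    damped log-CPM that keeps zeros finite.
    """
    sizes = (f.effective_sizes if f is not None else m.library_sizes).astype(float)
    if log_scale:
        return np.log2((m.counts + prior_count) / (sizes + 2.0 * prior_count) * 1e6)
    return m.counts * 1e6 / sizes


def filter_low_expression(
    m: CountMatrix,
    f: NormFactors | None = None,
    threshold: float = 1.0,
    use_raw_sizes: bool = True,
) -> CountMatrix:
    """Keep genes whose mean CPM across all samples is strictly above threshold.

    The filter precedes normalization by default (``use_raw_sizes=True``):
    mean CPM is computed against raw library sizes.  The retained-gene count
    is the background size for downstream enrichment.
    """
    if use_raw_sizes or f is None:
        mat = m.counts * 1e6 / m.library_sizes.astype(float)
    else:
        mat = cpm(m, f)
    keep = mat.mean(axis=1) > threshold
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    return m.subset_genes(m.gene_ids[keep])
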