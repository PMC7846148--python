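"""Per-gene negative binomial GLM engine.

Counts for gene g in sample i are modelled NB(mu_gi, phi_g) with log link

    log mu_gi = x_i' beta_g + offset_i,      Var = mu + phi * mu^2,

offset = ln(effective library size).  Dispersions phi are estimated by
maximizing the Cox-Reid adjusted profile likelihood on a grid (with
parabolic refinement) and shrunk toward a mean-expression trend.  Any
1-df linear hypothesis c'beta = 0 is tested by a likelihood ratio test:
the model is refit with the design projected onto the null space of c and
2 * delta-loglik referred to chi-square(1).

All fitting is vectorized across genes: one IRLS iteration updates every
gene simultaneously (batched p x p solves), which keeps multi-thousand-gene
analyses fast on a single core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io_qc import CountMatrix
from .normalization import NormFactors

_LN2 = np.log(2.0)
_ETA_CLIP = 50.0
_POISSON_PHI = 1e-8


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Treatment-coded design with ancestral at 15 C as baseline.

    ``group`` of a sample is its selection regime in the pooled model, or
    its population (ancestral pooled, each focal replicate its own level)
    in the replicate-specific model.  Columns: intercept, one indicator per
    non-baseline group, temperature (23 C), and group x temperature
    interactions.
    """

    X: np.ndarray
    coef_names: list[str]
    sample_ids: list[str]
    groups: list[str]          # group levels, baseline first

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is not full column rank")

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Build a contrast vector from {coefficient name: weight}."""
        c = np.zeros(self.n_coef)
        for name, w in weights.items():
            c[self.coef_names.index(name)] = w
        return c


def _build_design(samples: pd.DataFrame, group_labels: pd.Series) -> DesignMatrix:
    levels = sorted(set(group_labels), key=lambda g: (g != "ancestral", g))
    temp = (samples["assay_temperature"].astype(int) == 23).to_numpy(float)
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for lv in levels[1:]:
        cols.append((group_labels == lv).to_numpy(float))
        names.append(lv)
    temp_varies = 0.0 < temp.mean() < 1.0
    if temp_varies:
        cols.append(temp)
        names.append("temp23")
    for lv in levels[1:]:
        ind = (group_labels == lv).to_numpy(float)
        inter = ind * temp
        # only identifiable when the level is observed at both temperatures
        if temp_varies and 0.0 < inter.sum() < ind.sum():
            cols.append(inter)
            names.append(f"{lv}:temp23")
    return DesignMatrix(
        X=np.column_stack(cols),
        coef_names=names,
        sample_ids=list(samples.index),
        groups=levels,
    )


def main_design(samples: pd.DataFrame) -> DesignMatrix:
    """Regime x temperature design: ancestral / cold / hot, 15 vs 23 C."""
    return _build_design(samples, samples["regime"])


def replicate_design(samples: pd.DataFrame, focal_regime: str = "hot") -> DesignMatrix:
    """Population-level design for replicate-specific evolution.

    Ancestral populations form a single level; each focal-regime replicate
    is its own level (six levels for five replicates); other regimes must
    be excluded by the caller.
    """
    regimes = set(samples["regime"])
    if regimes - {"ancestral", focal_regime}:
        raise ValueError(
            "replicate design takes only ancestral and focal-regime samples"
        )
    labels = pd.Series(
        np.where(
            samples["regime"] == "ancestral",
            "ancestral",
            samples["regime"].astype(str) + "_rep" + samples["replicate"].astype(int).astype(str),
        ),
        index=samples.index,
    )
    return _build_design(samples, labels)


# ---------------------------------------------------------------------------
# likelihood and batched IRLS
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; phi below ~1e-8 is treated as Poisson."""
    y = np.asarray(y, float)
    mu = np.clip(mu, 1e-12, None)
    phi = np.asarray(phi, float)
    out = np.empty(y.shape[0])
    pois = phi <= _POISSON_PHI
    if pois.any():
        out[pois] = np.sum(
            y[pois] * np.log(mu[pois]) - mu[pois] - gammaln(y[pois] + 1.0), axis=1
        )
    nb = ~pois
    if nb.any():
        r = (1.0 / phi[nb])[:, None]
        yy, mm = y[nb], mu[nb]
        out[nb] = np.sum(
            gammaln(yy + r) - gammaln(r) - gammaln(yy + 1.0)
            - r * np.log1p(mm / r)
            + yy * (np.log(mm) - np.log(r + mm)),
            axis=1,
        )
    return out


def _irls_batch(
    Y: np.ndarray,
    X: np.ndarray,
    phi: np.ndarray,
    offsets: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Batched IRLS for NB regression with log link.

    Y (G, n); X (n, p); phi (G,); offsets (n,) or (G, n).
    Returns beta (G, p), loglik (G,), converged (G,), n_iter.
    """
    G, n = Y.shape
    p = X.shape[1]
    off = np.broadcast_to(np.asarray(offsets, float), (G, n))
    phi_col = phi[:, None]

    if beta0 is None:
        mu = np.clip(Y.astype(float), 0.5, None)
        eta = np.log(mu)
        lin = np.clip(eta - off, -_ETA_CLIP, _ETA_CLIP)
        beta = _wls_solve(X, np.ones_like(Y, float), lin)
    else:
        beta = beta0.copy()

    lin = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(lin + off)
    ll = nb_loglik(Y, mu, phi)
    converged = np.zeros(G, bool)
    it = 0
    for it in range(1, max_iter + 1):
        active = ~converged
        if not active.any():
            break
        W = mu / (1.0 + phi_col * mu)
        z = (lin + off) - off + (Y - mu) / np.clip(mu, 1e-12, None)
        beta_new = beta.copy()
        beta_new[active] = _wls_solve(X, W[active], z[active])
        lin_new = np.clip(beta_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu_new = np.exp(lin_new + off)
        ll_new = nb_loglik(Y, mu_new, phi)
        # step-halve genes whose likelihood worsened
        for _ in range(8):
            worse = active & (ll_new < ll - 1e-10)
            if not worse.any():
                break
            beta_new[worse] = 0.5 * (beta_new[worse] + beta[worse])
            lin_new[worse] = np.clip(beta_new[worse] @ X.T, -_ETA_CLIP, _ETA_CLIP)
            mu_new[worse] = np.exp(lin_new[worse] + off[worse])
            ll_new[worse] = nb_loglik(Y[worse], mu_new[worse], phi[worse])
        moved = np.abs(ll_new - ll) > tol * (np.abs(ll_new) + 1.0)
        improved = ll_new >= ll - 1e-10
        upd = active & improved
        beta[upd], ll[upd] = beta_new[upd], ll_new[upd]
        lin[upd], mu[upd] = lin_new[upd], mu_new[upd]
        converged = converged | (active & improved & ~moved) | (active & ~improved)
    return beta, ll, converged, it


def _wls_solve(X: np.ndarray, W: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Solve per-gene weighted least squares (batched normal equations)."""
    XtWX = np.einsum("gn,ni,nj->gij", W, X, X, optimize=True)
    XtWz = np.einsum("gn,ni,gn->gi", W, X, z, optimize=True)
    p = X.shape[1]
    XtWX = XtWX + 1e-10 * np.eye(p)
    return np.linalg.solve(XtWX, XtWz[..., None])[..., 0]


def fit_glm_batch(Y, X, phi, offsets, beta0=None, tol=1e-8, max_iter=100):
    """Fit the NB GLM for every gene; returns (beta, loglik, converged)."""
    beta, ll, conv, _ = _irls_batch(
        np.asarray(Y, float), X, np.asarray(phi, float), offsets, beta0, tol, max_iter
    )
    return beta, ll, conv


@dataclass
class GeneFit:
    """Single-gene NB GLM fit (coefficients on the natural-log scale)."""

    beta: np.ndarray
    dispersion: float
    loglik: float
    offsets: np.ndarray
    design: DesignMatrix
    counts: np.ndarray
    converged: bool


def fit_nb_glm(gene_counts, design: DesignMatrix, phi: float, offsets) -> GeneFit:
    """Maximum-likelihood NB fit for a single gene."""
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")
    y = np.asarray(gene_counts, float)[None, :]
    off = np.asarray(offsets, float)
    beta, ll, conv = fit_glm_batch(y, design.X, np.array([phi]), off)
    return GeneFit(
        beta=beta[0],
        dispersion=float(phi),
        loglik=float(ll[0]),
        offsets=off,
        design=design,
        counts=y[0],
        converged=bool(conv[0]),
    )


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    phi: pd.Series        # final (possibly shrunk) dispersions
    phi_raw: pd.Series    # per-gene Cox-Reid APL maximizers
    trend: pd.Series      # trend value per gene
    degenerate: pd.Series  # genes with no information (all-zero): trend used


def _cr_apl(Y, X, phi_val, offsets, beta0):
    """Cox-Reid adjusted profile log-likelihood at a common phi for all genes."""
    G = Y.shape[0]
    phi = np.full(G, phi_val)
    beta, ll, _, _ = _irls_batch(Y, X, phi, offsets, beta0, tol=1e-6, max_iter=40)
    off = np.broadcast_to(np.asarray(offsets, float), Y.shape)
    mu = np.exp(np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP) + off)
    W = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("gn,ni,nj->gij", W, X, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet, beta


def estimate_dispersion(
    m: CountMatrix,
    design: DesignMatrix,
    norm: NormFactors | None = None,
    shrink: str = "trend",
    prior_df: float = 20.0,
    n_bins: int = 20,
    grid: np.ndarray | None = None,
) -> DispersionEstimate:
    """Per-gene NB dispersion by Cox-Reid APL with trend shrinkage.

    The APL is evaluated on a log-spaced phi grid for every gene at once
    and the per-gene maximum refined by parabolic interpolation in log-phi.
    Raw estimates are shrunk toward the trend (median raw phi within
    mean-expression quantile bins) with weight residual-df / (residual-df +
    prior-df); ``shrink`` may be "trend", "common" (global median) or
    "none".  Genes with no counts carry no information and receive the
    trend value, flagged in ``degenerate``.
    """
    Y = m.counts.to_numpy(float)
    sizes = (norm.effective_sizes if norm is not None else m.library_sizes).to_numpy(float)
    offsets = np.log(sizes)
    X = design.X
    if grid is None:
        grid = np.logspace(-4, 1, 21)
    log_grid = np.log(grid)

    apl = np.empty((len(grid), Y.shape[0]))
    beta0 = None
    for k, phi_val in enumerate(grid):
        apl[k], beta0 = _cr_apl(Y, X, phi_val, offsets, beta0)

    best = np.argmax(apl, axis=0)
    phi_raw = grid[best].astype(float)
    # parabolic refinement on interior maxima (in log-phi)
    interior = (best > 0) & (best < len(grid) - 1)
    idx = np.where(interior)[0]
    if idx.size:
        b = best[idx]
        y0, y1, y2 = apl[b - 1, idx], apl[b, idx], apl[b + 1, idx]
        x0, x1, x2 = log_grid[b - 1], log_grid[b], log_grid[b + 1]
        denom = (y0 - y1) * (x1 - x2) - (y1 - y2) * (x0 - x1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vertex = 0.5 * (
                (y0 - y1) * (x1**2 - x2**2) - (y1 - y2) * (x0**2 - x1**2)
            ) / np.where(denom == 0, np.nan, denom)
        ok = np.isfinite(vertex) & (vertex >= x0) & (vertex <= x2)
        phi_raw[idx[ok]] = np.exp(vertex[ok])
    # boundary at the smallest grid value: effectively Poisson
    phi_raw[best == 0] = 0.0

    degenerate = Y.sum(axis=1) == 0

    # mean-expression trend
    mean_logcpm = np.log2(Y.sum(axis=1) / sizes.sum() * 1e6 + 0.25)
    informative = ~degenerate
    if shrink == "none":
        trend = np.zeros_like(phi_raw)
        phi_final = phi_raw.copy()
    elif shrink == "common":
        common = float(np.median(phi_raw[informative])) if informative.any() else 0.0
        trend = np.full_like(phi_raw, common)
        w = _shrink_weight(Y.shape[1], X.shape[1], prior_df)
        phi_final = w * phi_raw + (1 - w) * trend
    elif shrink == "trend":
        trend = _binned_trend(mean_logcpm, phi_raw, informative, n_bins)
        w = _shrink_weight(Y.shape[1], X.shape[1], prior_df)
        phi_final = w * phi_raw + (1 - w) * trend
    else:
        raise ValueError(f"unknown shrinkage mode: {shrink}")

    phi_final = np.where(degenerate, trend, phi_final)
    phi_final = np.clip(phi_final, 0.0, None)
    gi = m.gene_ids
    return DispersionEstimate(
        phi=pd.Series(phi_final, index=gi),
        phi_raw=pd.Series(phi_raw, index=gi),
        trend=pd.Series(trend, index=gi),
        degenerate=pd.Series(degenerate, index=gi),
    )


def _shrink_weight(n_samples: int, n_coef: int, prior_df: float) -> float:
    df_res = max(n_samples - n_coef, 1)
    return df_res / (df_res + prior_df)


def _binned_trend(mean_logcpm, phi_raw, informative, n_bins):
    trend = np.zeros_like(phi_raw)
    x = mean_logcpm[informative]
    if x.size == 0:
        return trend
    n_bins = min(n_bins, max(1, x.size // 10))
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    which = np.clip(np.searchsorted(edges, mean_logcpm, side="right") - 1, 0, len(edges) - 2)
    med = {}
    for b in range(len(edges) - 1):
        in_bin = informative & (which == b)
        med[b] = float(np.median(phi_raw[in_bin])) if in_bin.any() else np.nan
    vals = pd.Series(med).ffill().bfill().fillna(0.0)
    trend[:] = vals.reindex(which).to_numpy()
    return trend


# ---------------------------------------------------------------------------
# likelihood-ratio contrasts
# ---------------------------------------------------------------------------

def lrt_contrasts_batch(
    Y: np.ndarray,
    design: DesignMatrix,
    phi: np.ndarray,
    offsets: np.ndarray,
    contrast: np.ndarray,
    full_beta: np.ndarray | None = None,
    full_ll: np.ndarray | None = None,
):
    """LRT of c'beta = 0 for every gene.

    Returns (log2fc, lr, p, full_beta, full_ll); the full fit can be passed
    in to reuse across contrasts of the same family.
    """
    contrast = np.asarray(contrast, float)
    if contrast.shape != (design.n_coef,):
        raise ValueError("contrast length must equal the number of coefficients")
    if not contrast.any():
        raise ValueError("zero contrast vector")
    X = design.X
    if full_beta is None or full_ll is None:
        full_beta, full_ll, _ = fit_glm_batch(Y, X, phi, offsets)
    Z = sla.null_space(contrast[None, :])
    beta0 = full_beta @ Z  # project full solution into constrained space
    gamma, ll0, _, _ = _irls_batch(
        np.asarray(Y, float), X @ Z, np.asarray(phi, float), offsets, beta0
    )
    lr = np.clip(2.0 * (full_ll - ll0), 0.0, None)
    p = chi2.sf(lr, df=1)
    log2fc = (full_beta @ contrast) / _LN2
    return log2fc, lr, p, full_beta, full_ll


def lrt_contrast(fit: GeneFit, contrast) -> pd.Series:
    """Single-gene LRT of c'beta = 0; estimate reported as log2FC."""
    log2fc, lr, p, _, _ = lrt_contrasts_batch(
        fit.counts[None, :],
        fit.design,
        np.array([fit.dispersion]),
        fit.offsets,
        np.asarray(contrast, float),
        full_beta=fit.beta[None, :],
        full_ll=np.array([fit.loglik]),
    )
    return pd.Series({"log2fc": log2fc[0], "lr": lr[0], "p": p[0]})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (one family per call)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ContrastTable:
    """Named-contrast results for all genes: estimate, LR, p and BH q."""

    name: str
    table: pd.DataFrame  # index gene_id; columns log2fc, lr, p, q

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "contrast", self.name)
        out.to_csv(path, sep="\t", index_label="gene_id")


class GLMAnalysis:
    """A design + dispersions + full fit, from which contrasts are tested.

    Computes the shared full-model fit once; each named contrast then costs
    a single constrained refit and a BH adjustment across all genes.
    """

    def __init__(
        self,
        m: CountMatrix,
        design: DesignMatrix,
        norm: NormFactors | None = None,
        dispersion: DispersionEstimate | None = None,
        shrink: str = "trend",
    ):
        if list(m.counts.columns) != design.sample_ids:
            raise ValueError("design rows do not match count-matrix samples")
        self.m = m
        self.design = design
        sizes = (norm.effective_sizes if norm is not None else m.library_sizes)
        self.offsets = np.log(sizes.to_numpy(float))
        if dispersion is None:
            dispersion = estimate_dispersion(m, design, norm, shrink=shrink)
        self.dispersion = dispersion
        self.phi = dispersion.phi.to_numpy()
        Y = m.counts.to_numpy(float)
        self.full_beta, self.full_ll, self.converged = fit_glm_batch(
            Y, design.X, self.phi, self.offsets
        )
        self._Y = Y

    def test(self, name: str, weights: dict[str, float]) -> ContrastTable:
        c = self.design.contrast(weights)
        log2fc, lr, p, _, _ = lrt_contrasts_batch(
            self._Y, self.design, self.phi, self.offsets, c,
            full_beta=self.full_beta, full_ll=self.full_ll,
        )
        table = pd.DataFrame(
            {"log2fc": log2fc, "lr": lr, "p": p, "q": bh_adjust(p)},
            index=self.m.gene_ids,
        )
        return ContrastTable(name=name, table=table)

    def estimate(self, weights: dict[str, float]) -> pd.Series:
        """Point estimate c'beta / ln 2 (log2FC) without a test."""
        c = self.design.contrast(weights)
        return pd.Series((self.full_beta @ c) / _LN2, index=self.m.gene_ids)
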