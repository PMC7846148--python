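"""Reaction-norm evolution analysis.

Plasticity of a gene in a population group is the log2 fold change of its
expression at 23 C versus 15 C (the two-point reaction-norm slope).  The
analysis proceeds in three steps on a fitted regime x temperature NB GLM:

(a) within-group temperature contrasts call plastic genes (FDR < 0.05);
(b) evolved-vs-ancestral contrasts within each temperature call evolved
    expression changes (FDR < 0.05);
(c) among genes with an evolved change at >= 1 temperature (the candidate
    set), the interaction contrast (evolved slope - ancestral slope) is
    BH-adjusted within candidates at a more permissive FDR (< 0.1); a
    significant interaction is classified INCREASED or DECREASED plasticity
    by comparing |evolved slope| with |ancestral slope|, and candidates
    without a slope change but with same-sign significant shifts at both
    temperatures are CONSTITUTIVE; everything else is UNRESOLVED.

A false-positive guard re-tests each interaction-significant gene against
a hypothetical population that evolved expression at only one temperature
(the other temperature set to the ancestral value); the difference of that
hypothetical norm from the ancestral norm is algebraically the
single-temperature evolved contrast, so the guard passes iff at least one
single-temperature contrast is itself significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .nbglm import ContrastTable, GLMAnalysis, bh_adjust

CLASSES = ("INCREASED", "DECREASED", "CONSTITUTIVE", "UNRESOLVED")


class PlasticityAnalysis:
    """Step-wise contrasts and classification over a fitted GLM.

    ``group`` names refer to non-baseline design levels: "cold"/"hot" in
    the pooled regime model, "hot_rep1".."hot_rep5" in the replicate model;
    "ancestral" is the baseline.
    """

    def __init__(self, analysis: GLMAnalysis):
        self.glm = analysis
        self._cache: dict[str, ContrastTable] = {}

    # -- contrast vocabulary --------------------------------------------
    def _slope_weights(self, group: str) -> dict[str, float]:
        w = {"temp23": 1.0}
        if group != "ancestral":
            w[f"{group}:temp23"] = 1.0
        return w

    def _evolved_weights(self, group: str, temperature: int) -> dict[str, float]:
        if group == "ancestral":
            raise ValueError("evolved contrast against the ancestral baseline itself")
        w = {group: 1.0}
        if int(temperature) == 23:
            w[f"{group}:temp23"] = 1.0
        return w

    def _test(self, name: str, weights: dict[str, float]) -> ContrastTable:
        if name not in self._cache:
            self._cache[name] = self.glm.test(name, weights)
        return self._cache[name]

    # -- step (a): within-group plasticity ------------------------------
    def plasticity_test(self, group: str) -> ContrastTable:
        """23-vs-15 C contrast within a group (positive = higher at 23 C)."""
        if group not in self.glm.design.groups:
            raise ValueError(f"group {group!r} not in design ({self.glm.design.groups})")
        return self._test(f"plasticity_{group}", self._slope_weights(group))

    def call_plasticity(self, group: str, fdr: float = 0.05) -> pd.DataFrame:
        """Reaction norms of a group; ``plastic`` flags q < fdr genes."""
        t = self.plasticity_test(group).table
        out = t.rename(columns={"log2fc": "slope"}).copy()
        out["plastic"] = out["q"] < fdr
        return out

    # -- step (b): evolved expression -----------------------------------
    def evolved_test(self, group: str, temperature: int) -> ContrastTable:
        """Evolved-vs-ancestral contrast within one assay temperature."""
        return self._test(
            f"evolved_{group}_{int(temperature)}",
            self._evolved_weights(group, temperature),
        )

    def call_evolved_expression(
        self, group: str, temperature: int, fdr: float = 0.05
    ) -> pd.DataFrame:
        t = self.evolved_test(group, temperature).table
        out = t.copy()
        out["significant"] = out["q"] < fdr
        return out

    # -- step (c): interaction and classification ------------------------
    def interaction_test(self, group: str) -> ContrastTable:
        """Evolved slope minus ancestral slope (reaction-norm change)."""
        if group == "ancestral":
            raise ValueError("interaction is relative to the ancestral baseline")
        return self._test(f"interaction_{group}", {f"{group}:temp23": 1.0})

    def classify_reaction_norms(
        self,
        group: str,
        de_fdr: float = 0.05,
        interaction_fdr: float = 0.10,
        candidate_filter: bool = True,
    ) -> pd.DataFrame:
        """Classify candidate genes of a group into the plasticity classes.

        Returns one row per candidate gene (evolved DE at >= 1 temperature;
        with ``candidate_filter=False`` every retained gene is a candidate,
        which forgoes the false-positive protection of the restriction)
        with slopes, temperature-wise evolved shifts, q-values, the class
        and the false-positive-guard flags.  Summary counts are stored in
        ``.attrs``.
        """
        ev15 = self.evolved_test(group, 15).table
        ev23 = self.evolved_test(group, 23).table
        inter = self.interaction_test(group).table
        anc_slope = self.glm.estimate(self._slope_weights("ancestral"))
        evo_slope = self.glm.estimate(self._slope_weights(group))

        if candidate_filter:
            candidates = (ev15["q"] < de_fdr) | (ev23["q"] < de_fdr)
        else:
            candidates = pd.Series(True, index=ev15.index)
        cand_ids = ev15.index[candidates]
        # interaction family: BH within the candidate set only
        inter_q = pd.Series(np.nan, index=ev15.index)
        if len(cand_ids):
            inter_q.loc[cand_ids] = bh_adjust(inter.loc[cand_ids, "p"].to_numpy())

        table = pd.DataFrame(
            {
                "ancestral_slope": anc_slope.loc[cand_ids],
                "evolved_slope": evo_slope.loc[cand_ids],
                "delta15": ev15.loc[cand_ids, "log2fc"],
                "delta23": ev23.loc[cand_ids, "log2fc"],
                "q15": ev15.loc[cand_ids, "q"],
                "q23": ev23.loc[cand_ids, "q"],
                "interaction_p": inter.loc[cand_ids, "p"],
                "interaction_q": inter_q.loc[cand_ids],
            },
            index=cand_ids,
        )

        sig_inter = table["interaction_q"] < interaction_fdr
        more = table["evolved_slope"].abs() > table["ancestral_slope"].abs()
        less = table["evolved_slope"].abs() < table["ancestral_slope"].abs()
        same_sign = np.sign(table["delta15"]) == np.sign(table["delta23"])
        both_sig = (table["q15"] < de_fdr) & (table["q23"] < de_fdr)

        cls = np.full(len(table), "UNRESOLVED", dtype=object)
        cls[(sig_inter & more).to_numpy()] = "INCREASED"
        cls[(sig_inter & less).to_numpy()] = "DECREASED"
        constitutive = (~sig_inter) & same_sign & both_sig & (table["delta15"] != 0)
        cls[constitutive.to_numpy()] = "CONSTITUTIVE"
        table["class"] = cls

        # guard: the hypothetical population that evolved at only one
        # temperature has a norm differing from the ancestral norm by the
        # single-temperature contrast; test that contrast in the same
        # family as the interaction test (BH within candidates)
        if len(cand_ids):
            guard_q15 = pd.Series(bh_adjust(ev15.loc[cand_ids, "p"].to_numpy()), index=cand_ids)
            guard_q23 = pd.Series(bh_adjust(ev23.loc[cand_ids, "p"].to_numpy()), index=cand_ids)
        else:
            guard_q15 = guard_q23 = pd.Series(dtype=float)
        pass15 = guard_q15 < interaction_fdr
        pass23 = guard_q23 < interaction_fdr
        table["guard_q15"] = guard_q15
        table["guard_q23"] = guard_q23
        table["guard_pass15"] = np.where(sig_inter, pass15, np.nan)
        table["guard_pass23"] = np.where(sig_inter, pass23, np.nan)
        table["guard_pass"] = np.where(sig_inter, (pass15 | pass23), np.nan)

        table.attrs["group"] = group
        table.attrs["de_fdr"] = de_fdr
        table.attrs["interaction_fdr"] = interaction_fdr
        table.attrs["n_candidates"] = int(len(table))
        for c in CLASSES:
            table.attrs[f"n_{c.lower()}"] = int((table["class"] == c).sum())
        return table

    def false_positive_guard(self, gene_id: str, class_table: pd.DataFrame) -> dict:
        """Guard verdict for one interaction-significant candidate gene.

        The hypothetical population evolved at only one temperature has a
        reaction norm differing from the ancestral norm by exactly the
        single-temperature evolved contrast, so the guard at temperature T
        is that contrast's significance at the interaction FDR.
        """
        if gene_id not in class_table.index:
            raise ValueError(f"{gene_id} is not a candidate gene")
        row = class_table.loc[gene_id]
        if row["class"] not in ("INCREASED", "DECREASED"):
            raise ValueError(f"{gene_id} is not interaction-significant")
        return {
            "pass15": bool(row["guard_pass15"]),
            "pass23": bool(row["guard_pass23"]),
            "passed": bool(row["guard_pass"]),
        }


def direction_bias_test(n_increased: int, n_decreased: int) -> dict:
    """Is the increased:decreased split compatible with 50:50?

    Reports both a Wald test on the intercept of a binomial GLM (the
    modelling route) and the exact two-sided binomial test, plus the
    estimated probability of "increased".
    """
    n = n_increased + n_decreased
    if n < 1:
        raise ValueError("no classified genes to test")
    exact = stats.binomtest(n_increased, n, p=0.5, alternative="two-sided")
    p_hat = n_increased / n
    if 0 < n_increased < n:
        import statsmodels.api as sm

        endog = np.concatenate([np.ones(n_increased), np.zeros(n_decreased)])
        fit = sm.GLM(endog, np.ones((n, 1)), family=sm.families.Binomial()).fit()
        wald_p = float(fit.pvalues[0])
    else:
        wald_p = np.nan  # separated intercept: Wald undefined, exact test stands
    return {
        "n_increased": int(n_increased),
        "n_decreased": int(n_decreased),
        "proportion_increased": p_hat,
        "wald_p": wald_p,
        "exact_p": float(exact.pvalue),
    }


def sign_concordance_test(class_table: pd.DataFrame, cls: str = "INCREASED") -> dict:
    """Pearson chi-square of sign(delta15) x sign(delta23) in one class.

    Anti-concordance (opposite-sign evolved shifts at the two temperatures)
    loads the off-diagonal of the 2x2 table.  Genes with a zero shift at
    either temperature are excluded and counted.
    """
    if len(class_table) == 0:
        raise ValueError("empty class table")
    sub = class_table[class_table["class"] == cls]
    s15 = np.sign(sub["delta15"].to_numpy())
    s23 = np.sign(sub["delta23"].to_numpy())
    nonzero = (s15 != 0) & (s23 != 0)
    n_zero = int((~nonzero).sum())
    s15, s23 = s15[nonzero], s23[nonzero]
    if s15.size == 0:
        raise ValueError(f"no genes with nonzero shifts in class {cls}")
    a = int(np.sum((s15 > 0) & (s23 > 0)))
    b = int(np.sum((s15 > 0) & (s23 < 0)))
    c = int(np.sum((s15 < 0) & (s23 > 0)))
    d = int(np.sum((s15 < 0) & (s23 < 0)))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("degenerate 2x2 table (an all-zero margin)")
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "table": [[a, b], [c, d]],
        "chi2": float(chi2),
        "df": 1,
        "p": p,
        "n": n,
        "n_zero_excluded": n_zero,
    }


def restrict_to_ancestrally_plastic(
    class_table: pd.DataFrame, min_abs_slope: float = 1.0
) -> pd.DataFrame:
    """Subset of the class table with |ancestral slope| above a floor.

    Supports re-running the direction-bias test on genes that could have
    decreased plasticity in the first place.
    """
    return class_table[class_table["ancestral_slope"].abs() > min_abs_slope]
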