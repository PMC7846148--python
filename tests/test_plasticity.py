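import numpy as np
import pandas as pd
import pytest

from normevol.nbglm import GLMAnalysis, main_design
from normevol.plasticity import (
    PlasticityAnalysis,
    direction_bias_test,
    restrict_to_ancestrally_plastic,
    sign_concordance_test,
)

from conftest import make_matrix, make_samples


def deterministic_analysis(extra_genes=None, n_filler=20):
    """Noise-free dataset: counts equal their means exactly, two replicate
    populations per regime, so fitted group means match the planted values
    and class labels follow from the definitions alone."""
    samples = make_samples(n_reps=2, regimes=("ancestral", "hot"))
    # per-condition counts (anc15, anc23, hot15, hot23), identical across reps
    genes = {
        # ancestral slope -1, evolved slope -3 (delta15 +1, delta23 -1)
        "inc": (1600, 800, 3200, 400),
        # ancestral slope -2, evolved slope ~ -0.5
        "dec": (1600, 400, 800, 566),
        # no slope change, +1 log2FC at both temperatures
        "const": (500, 500, 1000, 1000),
    }
    if extra_genes:
        genes.update(extra_genes)
    for i in range(n_filler):
        genes[f"null{i}"] = (1000, 1000, 1000, 1000)
    order = samples.index
    cols = []
    for sid in order:
        regime = samples.loc[sid, "regime"]
        temp = samples.loc[sid, "assay_temperature"]
        k = {("ancestral", 15): 0, ("ancestral", 23): 1, ("hot", 15): 2, ("hot", 23): 3}[
            (regime, temp)
        ]
        cols.append([v[k] for v in genes.values()])
    counts = np.array(cols).T
    # balance the columns so raw library sizes are identical
    target = counts.sum(axis=0).max() + 10_000
    balance = target - counts.sum(axis=0)
    counts = np.vstack([counts, balance])
    m = make_matrix(counts, samples, gene_ids=list(genes) + ["balance"])
    an = GLMAnalysis(m, main_design(samples), shrink="none")
    return PlasticityAnalysis(an), m


class TestCallPlasticity:
    def test_flat_gene_not_called(self):
        pa, _ = deterministic_analysis()
        rn = pa.call_plasticity("ancestral")
        assert rn.loc["null0", "slope"] == pytest.approx(0.0, abs=1e-6)
        assert not rn.loc["null0", "plastic"]

    def test_slope_sign_convention_positive_higher_at_23(self):
        pa, _ = deterministic_analysis()
        rn = pa.call_plasticity("ancestral")
        # inc gene halves its expression from 15 to 23 C ancestrally
        assert rn.loc["inc", "slope"] == pytest.approx(-1.0, abs=1e-4)
        assert rn.loc["inc", "plastic"]

    def test_unknown_group_rejected(self):
        pa, _ = deterministic_analysis()
        with pytest.raises(ValueError):
            pa.call_plasticity("cold")

    def test_strong_planted_slopes_recovered(self, fitted_small_sim):
        _, m, truth, _, pa = fitted_small_sim
        rn = pa.call_plasticity("ancestral")
        tr = truth.loc[m.gene_ids]
        strong = tr["ancestral_slope"].abs() >= 2.0
        assert rn.loc[strong[strong].index, "plastic"].mean() >= 0.9

    def test_null_simulation_low_false_call_rate(self):
        from normevol.simulate import SimulationConfig, simulate_counts
        from normevol.io_qc import collapse_libraries

        cfg = SimulationConfig(
            n_genes=500, seed=21, fraction_plastic=0.0, fraction_increased=0.0,
            fraction_decreased=0.0, fraction_constitutive=0.0,
        )
        matrix, _ = simulate_counts(cfg)
        m = collapse_libraries(matrix)
        an = GLMAnalysis(m, main_design(m.samples))
        pa = PlasticityAnalysis(an)
        rn = pa.call_plasticity("ancestral")
        assert rn["plastic"].mean() <= 0.01


class TestEvolvedExpression:
    def test_ancestral_self_comparison_rejected(self):
        pa, _ = deterministic_analysis()
        with pytest.raises(ValueError):
            pa.call_evolved_expression("ancestral", 23)

    def test_constitutive_shift_detected_concordantly(self):
        pa, _ = deterministic_analysis()
        t15 = pa.call_evolved_expression("hot", 15)
        t23 = pa.call_evolved_expression("hot", 23)
        assert t15.loc["const", "significant"] and t23.loc["const", "significant"]
        assert t15.loc["const", "log2fc"] == pytest.approx(1.0, abs=1e-3)
        assert t23.loc["const", "log2fc"] == pytest.approx(1.0, abs=1e-3)

    def test_null_genes_not_called(self):
        pa, _ = deterministic_analysis()
        t23 = pa.call_evolved_expression("hot", 23)
        assert not t23.filter(like="null", axis=0)["significant"].any()


class TestClassification:
    def test_definitional_classes(self):
        pa, _ = deterministic_analysis()
        ct = pa.classify_reaction_norms("hot")
        assert ct.loc["inc", "class"] == "INCREASED"
        assert ct.loc["dec", "class"] == "DECREASED"
        assert ct.loc["const", "class"] == "CONSTITUTIVE"
        # the balance gene varies between conditions by construction and may
        # enter the candidate set alongside the three planted genes
        assert {"inc", "dec", "const"} <= set(ct.index)
        assert ct.attrs["n_candidates"] <= 4
        # increased plasticity here means a steeper negative slope
        assert ct.loc["inc", "ancestral_slope"] == pytest.approx(-1.0, abs=1e-3)
        assert ct.loc["inc", "evolved_slope"] == pytest.approx(-3.0, abs=1e-3)

    def test_classification_exhaustive_and_exclusive(self, fitted_small_sim):
        *_, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot")
        assert set(ct["class"]) <= {"INCREASED", "DECREASED", "CONSTITUTIVE", "UNRESOLVED"}
        counts = ct.attrs
        assert counts["n_candidates"] == (
            counts["n_increased"] + counts["n_decreased"]
            + counts["n_constitutive"] + counts["n_unresolved"]
        )

    def test_class_invariants_hold(self, fitted_small_sim):
        *_, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot", interaction_fdr=0.1)
        inc = ct[ct["class"] == "INCREASED"]
        dec = ct[ct["class"] == "DECREASED"]
        con = ct[ct["class"] == "CONSTITUTIVE"]
        assert (inc["interaction_q"] < 0.1).all()
        assert (inc["evolved_slope"].abs() > inc["ancestral_slope"].abs()).all()
        assert (dec["interaction_q"] < 0.1).all()
        assert (dec["evolved_slope"].abs() < dec["ancestral_slope"].abs()).all()
        assert (np.sign(con["delta15"]) == np.sign(con["delta23"])).all()
        assert ((con["q15"] < 0.05) & (con["q23"] < 0.05)).all()

    def test_planted_direction_recovered(self, fitted_small_sim):
        _, m, truth, _, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot")
        called = ct[ct["class"].isin(["INCREASED", "DECREASED"])]
        planted = truth.loc[called.index, "planted_class"]
        assert (planted == called["class"]).mean() >= 0.8


class TestGuard:
    def test_guard_soundness_exact(self, fitted_small_sim):
        # every guard-passing gene has a significant single-temperature
        # evolved contrast in the guard family
        *_, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot", interaction_fdr=0.1)
        passed = ct[ct["guard_pass"] == 1.0]
        assert (
            (passed["guard_q15"] < 0.1) | (passed["guard_q23"] < 0.1)
        ).all()

    def test_strong_single_temperature_gene_passes(self):
        pa, _ = deterministic_analysis()
        ct = pa.classify_reaction_norms("hot")
        verdict = pa.false_positive_guard("inc", ct)
        assert verdict["passed"]

    def test_true_increased_genes_pass_guard(self, fitted_small_sim):
        _, m, truth, _, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot")
        inc = ct[ct["class"] == "INCREASED"]
        true_inc = inc.index[truth.loc[inc.index, "planted_class"] == "INCREASED"]
        if len(true_inc) >= 5:
            assert ct.loc[true_inc, "guard_pass"].mean() >= 0.95

    def test_opposite_sign_noise_gene_fails_without_candidate_filter(self):
        # interaction significance produced by small opposite-sign shifts at
        # the two temperatures, neither single contrast being significant:
        # only reachable when the candidate restriction is lifted
        pa, _ = deterministic_analysis(
            extra_genes={"noise": (10000, 10000, 10206, 9798)}
        )
        ct_default = pa.classify_reaction_norms("hot")
        assert "noise" not in ct_default.index  # filtered by candidacy
        ct = pa.classify_reaction_norms("hot", candidate_filter=False)
        assert ct.loc["noise", "class"] in ("INCREASED", "DECREASED")
        assert ct.loc["noise", "guard_pass"] == 0.0

    def test_non_candidate_gene_rejected(self):
        pa, _ = deterministic_analysis()
        ct = pa.classify_reaction_norms("hot")
        with pytest.raises(ValueError):
            pa.false_positive_guard("null0", ct)


class TestDirectionBias:
    @pytest.mark.parametrize("n_inc,n_dec", [(241, 84), (62, 20)])
    def test_observed_splits_strongly_biased(self, n_inc, n_dec):
        res = direction_bias_test(n_inc, n_dec)
        assert res["exact_p"] < 0.001
        assert res["wald_p"] < 0.001
        assert res["proportion_increased"] > 0.5

    def test_symmetric_split_p_one(self):
        assert direction_bias_test(10, 10)["exact_p"] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_bias_test(0, 0)

    def test_ancestrally_plastic_restriction(self, fitted_small_sim):
        *_, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot")
        sub = restrict_to_ancestrally_plastic(ct, min_abs_slope=1.0)
        assert (sub["ancestral_slope"].abs() > 1.0).all()
        assert set(sub.index) <= set(ct.index)


class TestSignConcordance:
    def _table(self, cells):
        # cells = (n_pp, n_pm, n_mp, n_mm) for sign(d15) x sign(d23)
        rows = []
        for n, (s15, s23) in zip(cells, [(1, 1), (1, -1), (-1, 1), (-1, -1)]):
            rows += [{"delta15": s15, "delta23": s23, "class": "INCREASED"}] * n
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(sum(cells))])

    def test_perfect_anticoncordance_chi2_equals_n(self):
        res = sign_concordance_test(self._table((0, 50, 50, 0)))
        assert res["chi2"] == pytest.approx(100.0)
        assert res["p"] < 1e-20

    def test_independence_chi2_zero(self):
        res = sign_concordance_test(self._table((25, 25, 25, 25)))
        assert res["chi2"] == pytest.approx(0.0)

    def test_zero_deltas_excluded_and_counted(self):
        t = self._table((5, 5, 5, 5))
        t.loc["g0", "delta15"] = 0.0
        res = sign_concordance_test(t)
        assert res["n_zero_excluded"] == 1
        assert res["n"] == 19

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sign_concordance_test(pd.DataFrame(columns=["delta15", "delta23", "class"]))

    def test_planted_increased_genes_anticoncordant(self, fitted_small_sim):
        _, m, truth, _, pa = fitted_small_sim
        ct = pa.classify_reaction_norms("hot")
        if (ct["class"] == "INCREASED").sum() >= 10:
            res = sign_concordance_test(ct, "INCREASED")
            # anti-symmetric planting loads the off-diagonal
            (a, b), (c, d) = res["table"]
            assert b + c > a + d
            assert res["p"] < 0.05
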