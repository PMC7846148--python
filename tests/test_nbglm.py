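import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from normevol.io_qc import CountMatrix
from normevol.nbglm import (
    DesignMatrix,
    GLMAnalysis,
    bh_adjust,
    estimate_dispersion,
    fit_nb_glm,
    lrt_contrast,
    main_design,
    replicate_design,
)

from conftest import make_matrix, make_samples


def two_group_design(n_per_group=3):
    samples = make_samples(
        n_reps=n_per_group, regimes=("ancestral", "hot"), temperatures=(15,)
    )
    return main_design(samples), samples


class TestDesign:
    def test_main_design_coding(self):
        samples = make_samples(n_reps=2, regimes=("ancestral", "cold", "hot"))
        d = main_design(samples)
        assert d.coef_names == [
            "intercept", "cold", "hot", "temp23", "cold:temp23", "hot:temp23",
        ]
        assert d.X.shape == (12, 6)
        # ancestral at 15 C is the all-but-intercept-zero row
        anc15 = (samples["regime"] == "ancestral") & (samples["assay_temperature"] == 15)
        assert np.allclose(d.X[anc15.to_numpy()][:, 1:], 0.0)

    def test_replicate_design_six_levels(self):
        samples = make_samples(n_reps=5, regimes=("ancestral", "hot"))
        d = replicate_design(samples)
        assert d.groups == ["ancestral"] + [f"hot_rep{i}" for i in range(1, 6)]
        assert d.X.shape == (20, 12)

    def test_replicate_design_rejects_foreign_regimes(self):
        samples = make_samples(n_reps=2, regimes=("ancestral", "cold", "hot"))
        with pytest.raises(ValueError):
            replicate_design(samples)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(
                X=np.ones((4, 2)), coef_names=["a", "b"],
                sample_ids=list("abcd"), groups=[],
            )


class TestFit:
    def test_poisson_limit_matches_statsmodels_irls(self):
        # phi = 0 reduces to Poisson regression; statsmodels is the
        # independent IRLS oracle
        rng = np.random.default_rng(0)
        X = np.column_stack(
            [np.ones(12), rng.normal(size=12), rng.integers(0, 2, 12).astype(float)]
        )
        d = DesignMatrix(X=X, coef_names=["i", "x", "g"],
                         sample_ids=[f"s{i}" for i in range(12)], groups=[])
        offsets = np.log(rng.uniform(0.5, 2.0, 12))
        y = rng.poisson(np.exp(X @ [2.0, 0.5, -0.3] + offsets))
        fit = fit_nb_glm(y, d, phi=0.0, offsets=offsets)
        oracle = sm.GLM(y, X, family=sm.families.Poisson(), offset=offsets).fit()
        assert np.allclose(fit.beta, oracle.params, atol=1e-6)

    def test_two_group_log2fc_exact(self):
        d, _ = two_group_design()
        y = np.array([10, 10, 10, 20, 20, 20])
        fit = fit_nb_glm(y, d, phi=0.0, offsets=np.zeros(6))
        assert fit.beta[d.coef_names.index("hot")] / np.log(2) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_intercept_only_closed_form(self):
        X = np.ones((5, 1))
        d = DesignMatrix(X=X, coef_names=["i"],
                         sample_ids=[f"s{i}" for i in range(5)], groups=[])
        offsets = np.log(np.array([1.0, 2.0, 1.0, 3.0, 1.0]))
        y = np.array([3, 8, 2, 11, 5])
        fit = fit_nb_glm(y, d, phi=0.0, offsets=offsets)
        assert np.exp(fit.beta[0]) == pytest.approx(
            y.sum() / np.exp(offsets).sum(), rel=1e-8
        )

    def test_refit_from_solution_does_not_decrease_likelihood(self):
        d, _ = two_group_design()
        y = np.array([4, 9, 6, 14, 18, 11])
        fit = fit_nb_glm(y, d, phi=0.3, offsets=np.zeros(6))
        refit = fit_nb_glm(y, d, phi=0.3, offsets=np.zeros(6))
        assert refit.loglik >= fit.loglik - 1e-9
        assert fit.converged

    def test_negative_dispersion_rejected(self):
        d, _ = two_group_design()
        with pytest.raises(ValueError):
            fit_nb_glm(np.arange(6), d, phi=-0.1, offsets=np.zeros(6))


class TestDispersion:
    def _matrix(self, Y, n_samples):
        samples = make_samples(n_reps=n_samples // 2, regimes=("ancestral",))
        return (
            make_matrix(Y, samples),
            main_design(samples),
        )

    def test_poisson_counts_give_near_zero_phi(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(50, 500, 400)
        Y = rng.poisson(base[:, None], size=(400, 20))
        m, d = self._matrix(Y, 20)
        est = estimate_dispersion(m, d, shrink="none")
        assert est.phi_raw.median() <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(50, 500, 1000)
        r = 1 / 0.2
        Y = rng.negative_binomial(r, r / (r + base[:, None]), size=(1000, 20))
        m, d = self._matrix(Y, 20)
        est = estimate_dispersion(m, d, shrink="none")
        assert 0.15 <= est.phi_raw.median() <= 0.25

    def test_zero_count_gene_gets_trend_and_flag(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(100, size=(50, 10))
        Y[0] = 0
        m, d = self._matrix(Y, 10)
        est = estimate_dispersion(m, d, shrink="trend")
        g0 = m.gene_ids[0]
        assert est.degenerate[g0]
        assert est.phi[g0] == est.trend[g0]

    def test_shrinkage_pulls_single_gene_toward_trend(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(100, 200, 300)
        r = 1 / 0.1
        Y = rng.negative_binomial(r, r / (r + base[:, None]), size=(300, 10))
        m, d = self._matrix(Y, 10)
        est = estimate_dispersion(m, d, shrink="trend", prior_df=20.0)
        # shrunk estimates have lower spread than raw ones
        assert est.phi.std() < est.phi_raw.std()


class TestLRT:
    def test_null_coefficient_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        d, samples = two_group_design(n_per_group=5)
        G = 600
        base = rng.uniform(50, 500, G)
        r = 1 / 0.1
        Y = rng.negative_binomial(r, r / (r + base[:, None]), size=(G, 10))
        m = make_matrix(Y, samples)
        an = GLMAnalysis(m, d, shrink="none")
        res = an.test("null", {"hot": 1.0})
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_twofold_effect_recovered(self):
        rng = np.random.default_rng(6)
        d, samples = two_group_design(n_per_group=5)
        hot = (samples["regime"] == "hot").to_numpy()
        G = 400
        planted = np.zeros(G, bool)
        planted[:40] = True  # subset, so library sizes stay comparable
        base = rng.uniform(200, 800, G)
        fold = np.where(planted[:, None] & hot, 2.0, 1.0)
        r = 1 / 0.05
        Y = rng.negative_binomial(r, r / (r + base[:, None] * fold), size=(G, 10))
        m = make_matrix(Y, samples)
        an = GLMAnalysis(m, d, shrink="none")
        res = an.test("hot_effect", {"hot": 1.0}).table.iloc[:40]
        assert 0.8 <= res["log2fc"].median() <= 1.2
        assert (res["q"] < 0.05).mean() >= 0.8

    def test_identical_groups_lr_zero(self):
        d, _ = two_group_design()
        y = np.array([10, 10, 10, 10, 10, 10])
        fit = fit_nb_glm(y, d, phi=0.0, offsets=np.zeros(6))
        res = lrt_contrast(fit, d.contrast({"hot": 1.0}))
        assert res["lr"] == pytest.approx(0.0, abs=1e-8)
        assert res["p"] == pytest.approx(1.0, abs=1e-8)

    def test_zero_contrast_rejected(self):
        d, _ = two_group_design()
        fit = fit_nb_glm(np.arange(6) + 1, d, phi=0.0, offsets=np.zeros(6))
        with pytest.raises(ValueError):
            lrt_contrast(fit, np.zeros(d.n_coef))

    def test_lr_nonnegative_and_constrained_ll_not_higher(self):
        rng = np.random.default_rng(7)
        d, samples = two_group_design(n_per_group=4)
        Y = rng.poisson(rng.uniform(5, 200, (100, 1)), size=(100, 8))
        m = make_matrix(Y, samples)
        an = GLMAnalysis(m, d, shrink="none")
        res = an.test("c", {"hot": 1.0})
        assert (res.table["lr"] >= 0).all()

    def test_estimate_invariant_under_column_reordering(self):
        d, samples = two_group_design(n_per_group=4)
        rng = np.random.default_rng(8)
        y = rng.poisson(60, 8)
        fit = fit_nb_glm(y, d, phi=0.1, offsets=np.zeros(8))
        perm = [1, 0]
        d2 = DesignMatrix(
            X=d.X[:, perm], coef_names=[d.coef_names[i] for i in perm],
            sample_ids=d.sample_ids, groups=d.groups,
        )
        fit2 = fit_nb_glm(y, d2, phi=0.1, offsets=np.zeros(8))
        r1 = lrt_contrast(fit, d.contrast({"hot": 1.0}))
        r2 = lrt_contrast(fit2, d2.contrast({"hot": 1.0}))
        assert r1["log2fc"] == pytest.approx(r2["log2fc"], abs=1e-6)
        assert r1["lr"] == pytest.approx(r2["lr"], abs=1e-6)


def brute_force_bh(p):
    """q_i = min over k with p_(k) >= p_(i) of p_(k) * m / k (step-up)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return np.minimum(q, 1.0)


class TestBH:
    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_and_tied_pvalues(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])
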