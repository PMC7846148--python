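import numpy as np
import pandas as pd
import pytest

from normevol.io_qc import CountMatrix
from normevol.simulate import SimulationConfig, simulate_counts


def make_samples(
    n_reps: int = 1,
    regimes=("ancestral",),
    temperatures=(15, 23),
    n_libs: int = 1,
) -> pd.DataFrame:
    """Sample sheet for a hand-built CountMatrix."""
    rows = []
    for regime in regimes:
        prefix = {"ancestral": "anc"}.get(regime, regime)
        for rep in range(1, n_reps + 1):
            for temp in temperatures:
                for lib in range(1, n_libs + 1):
                    sid = f"{prefix}{rep}_{temp}" + (f"_L{lib}" if n_libs > 1 else "")
                    rows.append(
                        {
                            "sample_id": sid,
                            "population_id": f"{prefix}{rep}",
                            "regime": regime,
                            "replicate": rep,
                            "assay_temperature": temp,
                            "library_id": f"{sid}_lib",
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def make_matrix(counts: np.ndarray, samples: pd.DataFrame, gene_ids=None) -> CountMatrix:
    counts = np.asarray(counts)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples.index), samples
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest three-regime simulation with planted effects of every class."""
    cfg = SimulationConfig(
        n_genes=800,
        seed=11,
        fraction_increased=0.05,
        fraction_decreased=0.02,
        fraction_constitutive=0.01,
        magnification_factor=3.0,
        min_effect_slope=0.75,
    )
    matrix, truth = simulate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def fitted_small_sim(small_sim):
    """Collapsed, normalized, filtered and fitted version of ``small_sim``."""
    from normevol.io_qc import collapse_libraries
    from normevol.nbglm import GLMAnalysis, main_design
    from normevol.normalization import compute_tmm_factors, filter_low_expression
    from normevol.plasticity import PlasticityAnalysis

    cfg, matrix, truth = small_sim
    m = collapse_libraries(matrix)
    norm = compute_tmm_factors(m)
    m = filter_low_expression(m, norm)
    norm = compute_tmm_factors(m)
    analysis = GLMAnalysis(m, main_design(m.samples), norm)
    return cfg, m, truth, analysis, PlasticityAnalysis(analysis)
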