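"""Synthetic count matrices mimicking a thermal experimental-evolution study.

The generator emulates the design of a laboratory natural-selection
experiment: an ancestral population plus replicate populations evolved
under cold and hot regimes, each assayed in common gardens at 15 C and
23 C.  Per-gene expression follows a negative binomial model with log-link
mean structure

    mu = baseline_proportion * library_size * 2^(slope * I(23C)) * 2^(evolved effects)

where the ancestral reaction-norm slope (log2FC of 23 C over 15 C) is
planted for a configurable fraction of genes, and evolved populations
carry planted slope magnifications ("increased plasticity", anti-symmetric
shifts at the two temperatures), slope attenuations ("decreased
plasticity") or constitutive shifts (same shift at both temperatures).
Chorion/yolk-style marker genes can be spiked into selected libraries to
exercise the contamination filter.  A truth table records every planted
effect so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io_qc import CountMatrix

PLANTED_CLASSES = ("INCREASED", "DECREASED", "CONSTITUTIVE", "NULL_PLASTIC", "NULL_FLAT")


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the structure of the emulated experiment: 11,200
    expressed genes; five replicate populations per regime (ancestral
    reconstitutions included) assayed at 15 and 23 C; roughly 40% of genes
    ancestrally plastic; evolved effects planted in the hot regime at the
    rates reported for the real study (about 2% increased, 0.75% decreased
    plasticity, 0.45% constitutive shifts).
    """

    n_genes: int = 11_200
    n_replicates_per_regime: int = 5
    regimes: tuple[str, ...] = ("ancestral", "cold", "hot")
    temperatures: tuple[int, int] = (15, 23)
    baseline_log2cpm: tuple[float, float] = (4.0, 2.0)   # mean, sd
    dispersion_asymptote: float = 0.05                    # phi at high expression
    dispersion_slope: float = 2.0                         # phi ~ asym + slope/CPM
    library_size_range: tuple[float, float] = (8e6, 12e6)
    fraction_plastic: float = 0.40
    fraction_increased: float = 0.020
    fraction_decreased: float = 0.0075
    fraction_constitutive: float = 0.0045
    slope_distribution: tuple[float, float] = (0.0, 1.0)  # mean, sd of ancestral slopes
    min_effect_slope: float = 0.5        # |ancestral slope| floor for planted inc/dec genes
    magnification_factor: float = 2.0    # evolved slope = factor * ancestral (increased)
    attenuation_factor: float = 0.25     # evolved slope = factor * ancestral (decreased)
    constitutive_shift_log2fc: float = 1.0
    evolved_regimes: tuple[str, ...] = ("hot",)
    contamination_n_libraries: int = 0
    contamination_marker_fold: float = 16.0
    n_marker_genes: int = 12
    # markers (chorion/yolk-style genes) are near-silent in clean male
    # libraries: their summed CPM is pinned below the log2 screen threshold
    marker_total_cpm: float = 150.0
    two_libraries: bool = False          # two libraries per population x temperature
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "fraction_plastic": self.fraction_plastic,
            "fraction_increased": self.fraction_increased,
            "fraction_decreased": self.fraction_decreased,
            "fraction_constitutive": self.fraction_constitutive,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_increased + self.fraction_decreased > self.fraction_plastic:
            raise ConfigurationError(
                "planted increased+decreased genes must fit among plastic genes"
            )
        if (
            self.fraction_increased + self.fraction_decreased + self.fraction_constitutive
            > 1.0
        ):
            raise ConfigurationError("planted effect fractions exceed 1")
        if self.library_size_range[0] <= 0:
            raise ConfigurationError("library sizes must be positive")
        if self.n_genes <= self.n_marker_genes:
            raise ConfigurationError("n_genes must exceed n_marker_genes")
        if self.dispersion_asymptote < 0 or self.dispersion_slope < 0:
            raise ConfigurationError("dispersion trend parameters must be nonnegative")
        bad = set(self.evolved_regimes) - (set(self.regimes) - {"ancestral"})
        if bad:
            raise ConfigurationError(f"evolved effects in unknown regimes: {sorted(bad)}")

    # structured-text round trip
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in (
            "regimes", "temperatures", "baseline_log2cpm", "library_size_range",
            "slope_distribution", "evolved_regimes",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    n_reg = config.n_genes - config.n_marker_genes
    ids = [f"gene{str(i + 1).zfill(width)}" for i in range(n_reg)]
    ids += [f"marker{str(i + 1).zfill(2)}" for i in range(config.n_marker_genes)]
    return ids


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its truth table from the configuration.

    Returns ``(matrix, truth)`` where ``truth`` has one row per gene with
    the planted class, ancestral slope, evolved slope and temperature-wise
    shifts per evolved regime.  The same configuration and seed always
    produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n_markers = config.n_marker_genes
    n_regular = G - n_markers
    gene_ids = _gene_ids(config)

    # baseline expression: relative proportions from a log2-normal profile
    mu_l2, sd_l2 = config.baseline_log2cpm
    rel = np.power(2.0, rng.normal(mu_l2, sd_l2, size=G))
    if n_markers:
        # pin the markers' clean-library share to marker_total_cpm per million
        shape = np.power(2.0, rng.normal(0.0, 1.0, size=n_markers))
        frac = config.marker_total_cpm / 1e6
        rel[n_regular:] = (
            shape / shape.sum() * rel[:n_regular].sum() * frac / (1.0 - frac)
        )
    prop = rel / rel.sum()
    base_cpm = prop * 1e6
    phi = config.dispersion_asymptote + config.dispersion_slope / np.clip(base_cpm, 1e-3, None)

    # class assignment (markers always NULL_FLAT)
    n_plastic = int(round(config.fraction_plastic * G))
    n_inc = int(round(config.fraction_increased * G))
    n_dec = int(round(config.fraction_decreased * G))
    n_const = int(round(config.fraction_constitutive * G))
    n_plastic = min(n_plastic, n_regular)
    perm = rng.permutation(n_regular)
    plastic_idx = perm[:n_plastic]
    inc_idx = plastic_idx[:n_inc]
    dec_idx = plastic_idx[n_inc:n_inc + n_dec]
    nonplastic = perm[n_plastic:]
    const_idx = nonplastic[:n_const]

    s_mean, s_sd = config.slope_distribution
    anc_slope = np.zeros(G)
    anc_slope[plastic_idx] = rng.normal(s_mean, s_sd, size=n_plastic)
    # planted-effect genes must be appreciably plastic ancestrally
    for idx in (inc_idx, dec_idx):
        small = np.abs(anc_slope[idx]) < config.min_effect_slope
        while small.any():
            anc_slope[idx[small]] = rng.normal(s_mean, s_sd, size=int(small.sum()))
            small = np.abs(anc_slope[idx]) < config.min_effect_slope

    classes = np.array(["NULL_FLAT"] * G, dtype=object)
    classes[plastic_idx] = "NULL_PLASTIC"
    classes[inc_idx] = "INCREASED"
    classes[dec_idx] = "DECREASED"
    classes[const_idx] = "CONSTITUTIVE"

    const_shift = np.zeros(G)
    const_shift[const_idx] = config.constitutive_shift_log2fc * rng.choice(
        [-1.0, 1.0], size=const_idx.size
    )

    # per-regime temperature-wise evolved shifts (log2)
    delta15 = {r: np.zeros(G) for r in config.regimes if r != "ancestral"}
    delta23 = {r: np.zeros(G) for r in config.regimes if r != "ancestral"}
    evolved_slope = {r: anc_slope.copy() for r in config.regimes if r != "ancestral"}
    for r in config.evolved_regimes:
        d_inc = (config.magnification_factor - 1.0) * anc_slope[inc_idx]
        delta23[r][inc_idx] = 0.5 * d_inc
        delta15[r][inc_idx] = -0.5 * d_inc
        evolved_slope[r][inc_idx] = config.magnification_factor * anc_slope[inc_idx]
        d_dec = (config.attenuation_factor - 1.0) * anc_slope[dec_idx]
        delta23[r][dec_idx] = 0.5 * d_dec
        delta15[r][dec_idx] = -0.5 * d_dec
        evolved_slope[r][dec_idx] = config.attenuation_factor * anc_slope[dec_idx]
        delta15[r][const_idx] = const_shift[const_idx]
        delta23[r][const_idx] = const_shift[const_idx]

    # samples: regimes x replicates x temperatures x libraries
    lo, hi = config.library_size_range
    n_libs = 2 if config.two_libraries else 1
    sample_rows = []
    mean_cols = {}
    lib_order = []
    for regime in config.regimes:
        pop_prefix = {"ancestral": "anc", "cold": "cold", "hot": "hot"}.get(regime, regime)
        for rep in range(1, config.n_replicates_per_regime + 1):
            pop = f"{pop_prefix}{rep}"
            for temp in config.temperatures:
                for lib in range(1, n_libs + 1):
                    sid = f"{pop}_{temp}" + (f"_L{lib}" if n_libs > 1 else "")
                    lib_size = rng.uniform(lo, hi)
                    log2_mean = np.log2(prop) + np.log2(lib_size)
                    if temp == 23:
                        log2_mean = log2_mean + anc_slope
                    if regime != "ancestral":
                        log2_mean = log2_mean + (
                            delta23[regime] if temp == 23 else delta15[regime]
                        )
                    mean_cols[sid] = np.power(2.0, log2_mean)
                    lib_order.append(sid)
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "population_id": pop,
                            "regime": regime,
                            "replicate": rep,
                            "assay_temperature": temp,
                            "library_id": f"{sid}_lib",
                        }
                    )

    # contamination: boost marker-gene means in randomly chosen libraries
    contaminated = []
    if config.contamination_n_libraries > 0:
        contaminated = list(
            rng.choice(lib_order, size=config.contamination_n_libraries, replace=False)
        )
        marker_rows = slice(n_regular, G)
        for sid in contaminated:
            mean_cols[sid] = mean_cols[sid].copy()
            mean_cols[sid][marker_rows] *= config.contamination_marker_fold

    counts = {}
    r_par = 1.0 / phi
    for sid in lib_order:
        mu = mean_cols[sid]
        counts[sid] = rng.negative_binomial(r_par, r_par / (r_par + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    matrix = CountMatrix(counts_df, samples)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_class": classes,
            "ancestral_slope": anc_slope,
            "constitutive_shift": const_shift,
            "is_marker": [False] * n_regular + [True] * n_markers,
        }
    ).set_index("gene_id")
    for r in evolved_slope:
        truth[f"evolved_slope_{r}"] = evolved_slope[r]
        truth[f"delta15_{r}"] = delta15[r]
        truth[f"delta23_{r}"] = delta23[r]
    truth.attrs["contaminated_libraries"] = contaminated
    return matrix, truth


def marker_gene_ids(truth: pd.DataFrame) -> list[str]:
    """Gene ids of the planted contamination markers."""
    return list(truth.index[truth["is_marker"]])


def write_simulation(matrix: CountMatrix, truth: pd.DataFrame, outdir) -> None:
    """Write counts, sample sheet and truth table as TSV into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.write(outdir / "counts.tsv", outdir / "samples.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    with open(outdir / "markers.txt", "w") as fh:
        for g in marker_gene_ids(truth):
            fh.write(g + "\n")
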