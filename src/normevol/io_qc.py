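"""Count-matrix container, TSV I/O, and library-level quality control.

The raw input of the pipeline is a genes x samples table of nonnegative
integer read counts together with a sample sheet describing, for each
library, the population it came from, the selection regime of that
population (ancestral, cold- or hot-evolved), the replicate number and the
common-garden assay temperature.  Quality control consists of flagging
libraries contaminated with female transcripts (chorion / yolk-protein
marker genes), collapsing technical libraries of the same population and
temperature by summing counts, and optional depth equalization by
downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIMES = ("ancestral", "cold", "hot")
TEMPERATURES = (15, 23)

SAMPLESHEET_COLUMNS = [
    "sample_id",
    "population_id",
    "regime",
    "replicate",
    "assay_temperature",
    "library_id",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class QCError(RuntimeError):
    """Raised when a quality filter would leave no usable data."""


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, index = gene ids (unique),
        columns = sample ids.
    samples
        DataFrame indexed by sample id with columns ``population_id``,
        ``regime``, ``replicate``, ``assay_temperature`` and ``library_id``,
        in the same order as the count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dupes[:5])}")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise FormatError(
                f"count columns and sample sheet disagree; mismatched ids: {sorted(missing)[:5]}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts")
        bad = set(self.samples["regime"]) - set(REGIMES)
        if bad:
            raise FormatError(f"unknown regimes: {sorted(bad)}")
        bad_t = set(self.samples["assay_temperature"]) - set(TEMPERATURES)
        if bad_t:
            raise FormatError(f"unknown assay temperatures: {sorted(bad_t)}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        """Raw total counts per sample."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples.copy())

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)].copy()
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.samples.copy())

    # -- I/O -------------------------------------------------------------
    def write(self, counts_path, samplesheet_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        sheet = self.samples.reset_index(names="sample_id")
        sheet.to_csv(samplesheet_path, sep="\t", index=False)


def read_counts(counts_path, samplesheet_path) -> CountMatrix:
    """Read a TSV count matrix and its sample sheet into a CountMatrix.

    The count file has gene ids in the first column and one column per
    sample; the sample sheet has one row per sample with the columns of
    ``SAMPLESHEET_COLUMNS``.  Sample ids must match exactly (order is taken
    from the count file).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samplesheet_path, sep="\t")
    missing_cols = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise FormatError(f"sample sheet missing columns: {missing_cols}")
    sheet = sheet.set_index("sample_id")
    missing = [s for s in counts.columns if s not in sheet.index]
    extra = [s for s in sheet.index if s not in counts.columns]
    if missing or extra:
        raise FormatError(
            f"sample ids disagree between counts and sheet; "
            f"absent from sheet: {missing[:5]}; absent from counts: {extra[:5]}"
        )
    vals = counts.to_numpy()
    if not (np.issubdtype(vals.dtype, np.integer) or np.allclose(vals, np.round(vals))):
        raise FormatError("non-integer entries in count matrix")
    return CountMatrix(counts.astype(np.int64), sheet.loc[counts.columns].copy())


def marker_statistic(m: CountMatrix, marker_gene_ids, mode: str = "log2_of_sum") -> pd.Series:
    """Per-library contamination statistic over a set of marker genes.

    ``log2_of_sum`` (default): log2(1 + summed marker CPM) in each library.
    ``sum_of_log2``: sum over markers of log2(1 + CPM) — an alternative
    reading of "total log2 normalized expression".
    """
    present = [g for g in marker_gene_ids if g in m.gene_ids]
    if not present:
        raise FormatError("none of the marker genes are present in the matrix")
    cpm = m.counts.loc[present] * 1e6 / m.library_sizes
    if mode == "log2_of_sum":
        return np.log2(1.0 + cpm.sum(axis=0))
    if mode == "sum_of_log2":
        return np.log2(1.0 + cpm).sum(axis=0)
    raise ValueError(f"unknown marker statistic mode: {mode}")


def contamination_filter(
    m: CountMatrix,
    marker_gene_ids,
    threshold: float = 8.0,
    mode: str = "log2_of_sum",
):
    """Drop libraries whose marker-gene expression exceeds ``threshold``.

    Emulates the chorion / yolk-protein screen for female contamination:
    a library is flagged when its total log2-normalized marker expression
    is higher than the threshold (default eight, log2 units).

    Returns the filtered matrix and the list of flagged library sample ids.
    Missing marker ids are ignored (a warning is the caller's concern; at
    least one must be present).
    """
    stat = marker_statistic(m, marker_gene_ids, mode=mode)
    flagged = list(stat.index[stat > threshold])
    if len(flagged) == m.n_samples:
        raise QCError("contamination filter flagged every library")
    keep = [s for s in m.counts.columns if s not in flagged]
    return m.subset_samples(keep), flagged


def collapse_libraries(m: CountMatrix) -> CountMatrix:
    """Sum counts of libraries from the same (population, assay temperature).

    After collapsing there is exactly one measurement per population and
    temperature; total counts are conserved.  The collapsed sample id is
    ``<population_id>_<temperature>``.
    """
    key = list(
        zip(m.samples["population_id"], m.samples["assay_temperature"].astype(int))
    )
    groups: dict[tuple, list[str]] = {}
    for sid, k in zip(m.counts.columns, key):
        groups.setdefault(k, []).append(sid)
    new_cols = {}
    meta_rows = []
    for (pop, temp), sids in groups.items():
        new_id = f"{pop}_{temp}"
        new_cols[new_id] = m.counts[sids].sum(axis=1)
        first = m.samples.loc[sids[0]]
        meta_rows.append(
            {
                "sample_id": new_id,
                "population_id": pop,
                "regime": first["regime"],
                "replicate": first["replicate"],
                "assay_temperature": temp,
                "library_id": "+".join(str(m.samples.loc[s, "library_id"]) for s in sids),
            }
        )
    counts = pd.DataFrame(new_cols, index=m.gene_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts, samples)


def downsample_counts(m: CountMatrix, target_depth: int, seed: int) -> CountMatrix:
    """Subsample each library without replacement to ``target_depth`` reads.

    Sampling is multivariate hypergeometric per column, so counts stay
    integral and expected per-gene proportions are preserved.  Columns whose
    total is already at or below the target are left unchanged.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    rng = np.random.default_rng(seed)
    out = m.counts.copy()
    for col in out.columns:
        colvals = out[col].to_numpy()
        total = int(colvals.sum())
        if total <= target_depth:
            continue
        out[col] = rng.multivariate_hypergeometric(colvals, target_depth)
    return CountMatrix(out, m.samples.copy())


def read_marker_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids
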