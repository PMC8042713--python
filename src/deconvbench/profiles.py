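"""Cell-type expression profiles: containers, I/O, filtering, unit conversion.

The central container is :class:`ExpressionMatrix`, a gene x sample table with
a declared quantification unit (count, countNorm, cpm, tpm or fpkm).
:class:`SourceProfiles` bundles per-cell-type mean profiles (the ``S`` matrix
of the mixture model ``M = S x W + eps``) with the purified replicate samples
they were derived from, so references can be rebuilt from the same material.

A synthetic profile generator stands in for purified immune-cell RNA-seq
datasets: it embeds disjoint marker-gene blocks per cell type so that marker
selection and deconvolution have recoverable structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UNITS",
    "ExpressionMatrix",
    "SourceProfiles",
    "generate_source_profiles",
    "filter_low_abundance",
    "convert_units",
    "build_reference",
    "read_expression_tsv",
    "write_expression_tsv",
]

#: Recognized quantification units.
UNITS = ("count", "countNorm", "cpm", "tpm", "fpkm")

#: Default minimum-expression thresholds per unit for low-abundance filtering.
DEFAULT_MIN_EXPR = {"count": 10.0, "countNorm": 10.0, "cpm": 1.0, "tpm": 1.0, "fpkm": 1.0}


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression table.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    unit
        One of ``count``, ``countNorm``, ``cpm``, ``tpm``, ``fpkm``.
    gene_lengths
        Optional per-gene feature lengths in kilobases, aligned to the index.
        Required for conversions involving tpm.
    """

    values: pd.DataFrame
    unit: str = "count"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            # Ingestion contract: duplicated gene ids keep the first occurrence.
            self.values = self.values.loc[~self.values.index.duplicated(keep="first")]
        if self.gene_lengths is not None:
            self.gene_lengths = pd.Series(self.gene_lengths).reindex(self.values.index)
            if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive and cover every gene")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return ExpressionMatrix(self.values.loc[genes], unit=self.unit, gene_lengths=lengths)


@dataclass
class SourceProfiles:
    """Per-cell-type expected expression (S matrix) plus purified replicates."""

    mean_profiles: pd.DataFrame  # genes x cell types
    replicates: dict[str, ExpressionMatrix]
    dataset_tag: str = "synthetic"
    gene_lengths: pd.Series | None = None
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ct in self.mean_profiles.columns:
            if ct not in self.replicates or self.replicates[ct].n_samples < 1:
                raise ValueError(f"cell type {ct!r} has no replicate samples")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_profiles.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.mean_profiles.index


def generate_source_profiles(
    n_genes: int,
    cell_types: list[str],
    marker_frac: float = 0.02,
    marker_fold: float = 50.0,
    n_replicates: int = 5,
    seed: int = 0,
    base_mean: float = 200.0,
    dispersion: float = 0.05,
    dataset_tag: str = "synthetic",
) -> SourceProfiles:
    """Generate synthetic purified cell-type profiles with embedded markers.

    Each cell type owns a disjoint block of ``round(marker_frac * n_genes)``
    marker genes whose mean expression in the owning type is ``marker_fold``
    times its expression in every other type. Background gene means are drawn
    from a log-normal to mimic the skewed abundance distribution of RNA-seq.
    Replicate purified samples are negative-binomial draws around the means
    with a mild per-gene dispersion, so marker selection sees realistic
    within-type variability. Gene lengths (kb) are drawn log-uniformly in
    [0.5, 10] and fixed by the seed; only the tpm-vs-cpm contrast matters.

    Fully determined by ``seed``: identical calls give identical outputs.
    """
    K = len(cell_types)
    if K < 1:
        raise ValueError("need at least one cell type")
    if len(set(cell_types)) != K:
        raise ValueError("cell type labels must be unique")
    if n_genes < 10 * K:
        raise ValueError(f"n_genes must be at least 10 x K = {10 * K}")
    if marker_fold < 1:
        raise ValueError("marker_fold must be >= 1")
    n_markers = int(round(marker_frac * n_genes))
    if n_markers < 2:
        raise ValueError(
            "marker budget too small: "
            f"marker_frac x n_genes = {marker_frac * n_genes:.2f} < 2 per cell type"
        )
    if n_markers * K > n_genes:
        raise ValueError("marker blocks exceed the gene count")

    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"gene_{i:05d}" for i in range(n_genes)], name="gene_id")

    # Background: shared log-normal baseline, mildly jittered per cell type so
    # non-marker genes are correlated but not identical across types.
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    means = np.empty((n_genes, K))
    for k in range(K):
        means[:, k] = base * rng.lognormal(mean=0.0, sigma=0.1, size=n_genes)

    marker_map: dict[str, list[str]] = {}
    order = rng.permutation(n_genes)
    for k, ct in enumerate(cell_types):
        idx = order[k * n_markers : (k + 1) * n_markers]
        # Exact fold contract: owner mean = marker_fold x the (common) level
        # in every other type. The low level sits in the lower half of the
        # abundance distribution, the way true lineage markers are silenced
        # outside their lineage rather than merely halved.
        low = base_mean * rng.lognormal(np.log(0.3), 0.3, size=idx.size)
        for kk in range(K):
            means[idx, kk] = low
        means[idx, k] = low * marker_fold
        marker_map[ct] = [gene_ids[i] for i in sorted(idx)]

    gene_lengths = pd.Series(
        np.exp(rng.uniform(np.log(0.5), np.log(10.0), size=n_genes)),
        index=gene_ids,
        name="length_kb",
    )

    mean_df = pd.DataFrame(means, index=gene_ids, columns=cell_types)
    replicates: dict[str, ExpressionMatrix] = {}
    for k, ct in enumerate(cell_types):
        mu = means[:, k][:, None]
        # Gamma-Poisson draws: shape 1/dispersion gives CV ~ sqrt(dispersion).
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape, size=(n_genes, n_replicates))
        counts = rng.poisson(lam).astype(float)
        df = pd.DataFrame(
            counts,
            index=gene_ids,
            columns=[f"{dataset_tag}_{ct}_rep{r}" for r in range(n_replicates)],
        )
        replicates[ct] = ExpressionMatrix(df, unit="count", gene_lengths=gene_lengths)

    return SourceProfiles(
        mean_profiles=mean_df,
        replicates=replicates,
        dataset_tag=dataset_tag,
        gene_lengths=gene_lengths,
        marker_genes=marker_map,
    )


def filter_low_abundance(
    m: ExpressionMatrix,
    min_samples: int = 5,
    min_expr: float | None = None,
) -> ExpressionMatrix:
    """Drop genes not strictly exceeding ``min_expr`` in >= ``min_samples`` samples.

    ``min_expr`` defaults per unit: 10 for count/countNorm, 1 for tpm/cpm/fpkm.
    "More than" is a strict inequality, so a gene at exactly the threshold in a
    sample does not count that sample. The sample set is unchanged.
    """
    if min_samples > m.n_samples:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {m.n_samples}")
    if min_samples < 1:
        raise ValueError("min_samples must be positive")
    if min_expr is None:
        min_expr = DEFAULT_MIN_EXPR[m.unit]
    keep = (m.values > min_expr).sum(axis=1) >= min_samples
    lengths = None if m.gene_lengths is None else m.gene_lengths[keep]
    return ExpressionMatrix(m.values.loc[keep], unit=m.unit, gene_lengths=lengths)


def filter_low_abundance_concat(
    matrices: list[ExpressionMatrix],
    min_samples: int = 10,
    min_expr: float | None = None,
) -> list[ExpressionMatrix]:
    """Concatenated-mode filtering: pool samples, filter once, apply to all.

    Used when several datasets enter one benchmark so every matrix retains the
    same gene set. All inputs must share unit and gene index.
    """
    if not matrices:
        raise ValueError("no matrices given")
    unit = matrices[0].unit
    idx = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.unit != unit or not m.gene_ids.equals(idx):
            raise ValueError("matrices must share unit and gene index")
    pooled = pd.concat([m.values for m in matrices], axis=1)
    pooled_m = ExpressionMatrix(pooled, unit=unit, gene_lengths=matrices[0].gene_lengths)
    kept = filter_low_abundance(pooled_m, min_samples=min_samples, min_expr=min_expr).gene_ids
    return [m.subset_genes(kept) for m in matrices]


def convert_units(m: ExpressionMatrix, target: str) -> ExpressionMatrix:
    """Convert a count matrix to countNorm, cpm or tpm.

    Per sample j with counts c_i and gene lengths L_i (kb):

    * cpm_i       = c_i / sum(c) * 1e6
    * countNorm_i = c_i / sum(c) * L_median   (L_median = median library size)
    * tpm_i       = (c_i / L_i) / sum(c_i' / L_i') * 1e6
    """
    if target not in UNITS:
        raise ValueError(f"unknown target unit {target!r}")
    if target == m.unit:
        return m
    if m.unit != "count":
        raise ValueError(f"conversions start from count, not {m.unit!r}")
    lib = m.values.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size in samples: {bad}")
    if target == "cpm":
        out = m.values / lib * 1e6
    elif target == "countNorm":
        out = m.values / lib * float(np.median(lib))
    elif target == "tpm":
        if m.gene_lengths is None:
            raise ValueError("gene_lengths required for tpm conversion")
        rate = m.values.div(m.gene_lengths, axis=0)
        out = rate / rate.sum(axis=0) * 1e6
    else:
        raise ValueError(f"conversion count -> {target} is not supported")
    return ExpressionMatrix(out, unit=target, gene_lengths=m.gene_lengths)


def build_reference(src: SourceProfiles, include: list[str]) -> ExpressionMatrix:
    """Mean expression of purified replicates for the included cell types.

    Unknown mixture components (e.g. a tumor spike-in line) are excluded from
    references simply by leaving them out of ``include``.
    """
    if not include:
        raise ValueError("include must name at least one cell type")
    missing = [ct for ct in include if ct not in src.cell_types]
    if missing:
        raise ValueError(f"cell types not in source: {missing}")
    cols = {ct: src.replicates[ct].values.mean(axis=1) for ct in include}
    ref = pd.DataFrame(cols, index=src.gene_ids)
    return ExpressionMatrix(ref, unit="count", gene_lengths=src.gene_lengths)


# ---------------------------------------------------------------------------
# TSV I/O (gene x sample table; unit in a sidecar JSON)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep="\t")
    meta = {"unit": m.unit}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    if m.gene_lengths is not None:
        m.gene_lengths.to_csv(path.with_suffix(".lengths.tsv"), sep="\t", header=True)


def read_expression_tsv(
    path: str | Path,
    unit: str | None = None,
    lengths_path: str | Path | None = None,
) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if unit is None:
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        unit = json.loads(meta_path.read_text())["unit"] if meta_path.exists() else "count"
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(df, unit=unit, gene_lengths=lengths)
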