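"""Marker-gene and signature-gene selection.

Marker genes are selected by per-sample percentile rank: a gene marks cell
type T when it sits above the 80th expression percentile within enough of T's
purified samples and below the 50th percentile within enough samples of every
other type. The required sample fraction p starts at 0.95 and is relaxed in
steps of s = 0.03 until every type owns at least two markers — mirroring how
marker criteria must loosen as the component roster grows.

Signature genes come from pairwise differential expression: any gene with
adjusted p <= 0.01 and |log2 fold change| >= the threshold in at least one
cell-type pair (union rule; intersection available). A Welch-t test on
log2(CPM + 1) is provided as the built-in DE engine; any external per-gene DE
table in the same schema can be supplied instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ExpressionMatrix

__all__ = [
    "MarkerCriteria",
    "markers_at_fraction",
    "select_markers",
    "de_test_default",
    "de_test_all_pairs",
    "select_signature",
]


@dataclass
class MarkerCriteria:
    high_pct: float = 80.0  # percentile the gene must exceed in the owner type
    low_pct: float = 50.0  # percentile it must stay below elsewhere
    p: float = 0.95  # initial required sample fraction
    s: float = 0.03  # relaxation step
    min_markers: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.low_pct < self.high_pct < 100:
            raise ValueError("need 0 < low_pct < high_pct < 100")
        if not 0 < self.s < self.p <= 1:
            raise ValueError("need 0 < s < p <= 1")
        if self.min_markers < 1:
            raise ValueError("min_markers must be positive")


def _percentile_masks(
    m: ExpressionMatrix, high_pct: float, low_pct: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample boolean masks: above the high and below the low percentile.

    Percentiles are computed across genes within each sample (column-wise),
    which makes the criterion rank-based and quantification-unit-invariant.
    """
    v = m.values.to_numpy()
    hi = np.percentile(v, high_pct, axis=0, keepdims=True)
    lo = np.percentile(v, low_pct, axis=0, keepdims=True)
    return v > hi, v < lo


def _marker_fractions(
    replicates: dict[str, ExpressionMatrix], crit: MarkerCriteria
) -> tuple[pd.Index, dict[str, np.ndarray], dict[str, np.ndarray]]:
    cell_types = list(replicates)
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types")
    idx = next(iter(replicates.values())).gene_ids
    for m in replicates.values():
        if not m.gene_ids.equals(idx):
            raise ValueError("replicate matrices must share one gene index")
    high_frac, low_frac = {}, {}
    for ct, m in replicates.items():
        hi, lo = _percentile_masks(m, crit.high_pct, crit.low_pct)
        high_frac[ct] = hi.mean(axis=1)
        low_frac[ct] = lo.mean(axis=1)
    return idx, high_frac, low_frac


def markers_at_fraction(
    replicates: dict[str, ExpressionMatrix],
    p: float,
    criteria: MarkerCriteria | None = None,
) -> dict[str, list[str]]:
    """Marker sets at one fixed sample fraction p, without relaxation."""
    crit = criteria or MarkerCriteria()
    idx, high_frac, low_frac = _marker_fractions(replicates, crit)
    markers: dict[str, list[str]] = {}
    for ct in replicates:
        ok = high_frac[ct] >= p - 1e-12
        for other in replicates:
            if other != ct:
                ok &= low_frac[other] >= p - 1e-12
        markers[ct] = list(idx[ok])
    return markers


def select_markers(
    replicates: dict[str, ExpressionMatrix],
    criteria: MarkerCriteria | None = None,
) -> dict[str, list[str]]:
    """Select marker genes per cell type with the percentile + relaxation rule.

    At sample fraction p, gene g marks type T iff the fraction of T's samples
    where g exceeds the per-sample high percentile is >= p, and for every
    other type the fraction of samples where g falls below the per-sample low
    percentile is >= p. p relaxes by s until every type has min_markers
    markers; exhausting p raises with the failing types named.
    """
    crit = criteria or MarkerCriteria()
    cell_types = list(replicates)
    idx, high_frac, low_frac = _marker_fractions(replicates, crit)

    p = crit.p
    while True:
        markers: dict[str, list[str]] = {}
        # tiny tolerance: p accumulates float error over relaxation steps
        for ct in cell_types:
            ok = high_frac[ct] >= p - 1e-12
            for other in cell_types:
                if other != ct:
                    ok &= low_frac[other] >= p - 1e-12
            markers[ct] = list(idx[ok])
        short = [ct for ct in cell_types if len(markers[ct]) < crit.min_markers]
        if not short:
            break
        p -= crit.s
        if p <= 0:
            raise ValueError(
                f"no marker genes found for cell types {short} even at p -> 0"
            )

    # High-in-owner and low-everywhere-else cannot hold for two owners at
    # p > 0.5; guard the contract anyway for relaxed p.
    seen: dict[str, str] = {}
    for ct, genes in markers.items():
        for g in genes:
            if g in seen:
                raise RuntimeError(f"gene {g} marks both {seen[g]} and {ct}")
            seen[g] = ct
    return markers


def _cpm_log2(m: ExpressionMatrix) -> np.ndarray:
    v = m.values.to_numpy()
    lib = v.sum(axis=0, keepdims=True)
    if (lib == 0).any():
        raise ValueError("zero library size sample")
    return np.log2(v / lib * 1e6 + 1.0)


def de_test_default(
    replicates_a: ExpressionMatrix,
    replicates_b: ExpressionMatrix,
    pair_label: str = "a_vs_b",
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(CPM + 1) with BH adjustment.

    Returns a DataFrame with columns pair, gene_id, log2fc, pvalue, padj.
    log2fc is the difference of transformed group means (a minus b). Genes
    with zero variance in both groups and equal means get p = 1.
    """
    if replicates_a.n_samples < 2 or replicates_b.n_samples < 2:
        raise ValueError("need at least two replicates per side")
    if not replicates_a.gene_ids.equals(replicates_b.gene_ids):
        raise ValueError("gene indexes differ between the two groups")
    a, b = _cpm_log2(replicates_a), _cpm_log2(replicates_b)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(pvals)
    # zero within-group variance everywhere: call equal means non-significant,
    # unequal means maximally significant
    pvals = np.where(degenerate, np.where(np.abs(lfc) > 0, 0.0, 1.0), pvals)
    padj = _benjamini_hochberg(pvals)
    return pd.DataFrame({
        "pair": pair_label,
        "gene_id": replicates_a.gene_ids,
        "log2fc": lfc,
        "pvalue": pvals,
        "padj": padj,
    })


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def de_test_all_pairs(replicates: dict[str, ExpressionMatrix]) -> pd.DataFrame:
    """Run the default DE test on every unordered cell-type pair."""
    if len(replicates) < 2:
        raise ValueError("need at least two cell types")
    frames = [
        de_test_default(replicates[a], replicates[b], pair_label=f"{a}_vs_{b}")
        for a, b in itertools.combinations(replicates, 2)
    ]
    return pd.concat(frames, ignore_index=True)


def select_signature(
    de: pd.DataFrame,
    padj_max: float = 0.01,
    lfc_min: float = 10.0,
    rule: str = "union",
) -> list[str]:
    """Genes passing padj <= padj_max and |log2fc| >= lfc_min.

    ``union`` keeps genes passing in at least one pair; ``intersection``
    requires passing in every pair. The default fold-change threshold is the
    extreme 2**10; real signature construction on moderate effect sizes will
    want a smaller value.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown rule {rule!r}")
    passing = de[(de["padj"] <= padj_max) & (de["log2fc"].abs() >= lfc_min)]
    if rule == "union":
        genes = pd.unique(passing["gene_id"])
    else:
        n_pairs = de["pair"].nunique()
        counts = passing.groupby("gene_id")["pair"].nunique()
        genes = counts.index[counts == n_pairs].to_numpy()
    return sorted(genes)
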