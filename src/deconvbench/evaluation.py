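"""Dual-metric, dual-scale scoring of deconvolution estimates.

Each cell type in a mixture set is scored across samples with two metrics:

* Pearson correlation r between estimated and true proportions — captures
  whether the linear trend is recovered, but is blind to systematic offset;
* mean absolute deviance mAD = sum |x_j - y_j| / J — captures the offset.

Failures are penalized at the worst attainable values: any NA estimate, and
any r that is undefined because a vector is constant (e.g. an all-zero
estimate for a varying cell type), scores r = -1 and mAD = 1. Penalized
values participate in downstream averaging and ranking.

With unknown (tumor) content the truth comes in two scales: absolute (immune
fractions of the whole mixture, summing to 1 - t per sample) and relative
(renormalized over known cell types, summing to 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .deconv import ProportionEstimate
from .weights import WeightMatrix

__all__ = [
    "pearson_r",
    "mad",
    "evaluate_celltype",
    "ground_truth_scales",
    "summarize",
    "rank_methods",
]

PENALTY_R = -1.0
PENALTY_MAD = 1.0


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.isnan(x).any() or np.isnan(y).any():
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def mad(x, y) -> float:
    """Mean absolute deviance between two proportion vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.abs(x - y).mean())


def evaluate_celltype(
    est: ProportionEstimate,
    truth: WeightMatrix,
    scale: str = "relative",
    condition: dict | None = None,
    include_all: bool = True,
) -> pd.DataFrame:
    """Per-cell-type r and mAD rows for one estimate against one truth.

    NA estimates and undefined correlations receive the worst-case penalty
    (r = -1, mAD = 1). mAD is computed over non-NA samples when any remain,
    and penalized outright when a cell type has no usable estimate at all.
    The ``all`` row is the unweighted mean over cell types.
    """
    if scale not in ("relative", "absolute"):
        raise ValueError(f"unknown scale {scale!r}")
    roster = truth.cell_types
    have = set(est.cell_types)
    if have != set(roster):
        raise ValueError(
            "cell-type roster mismatch: "
            f"extra={sorted(have - set(roster))}, missing={sorted(set(roster) - have)}"
        )
    est_v = est.values.loc[roster]
    truth_v = truth.values
    if list(est_v.columns) != list(truth_v.columns):
        if est_v.shape[1] != truth_v.shape[1]:
            raise ValueError("sample counts differ between estimate and truth")
        est_v = est_v.set_axis(truth_v.columns, axis=1)

    rows = []
    for ct in roster:
        x = est_v.loc[ct].to_numpy(dtype=float)
        y = truth_v.loc[ct].to_numpy(dtype=float)
        na = np.isnan(x)
        if na.any():
            r_val, mad_val = PENALTY_R, PENALTY_MAD
        else:
            r_val = pearson_r(x, y)
            if np.isnan(r_val):
                r_val = PENALTY_R
            mad_val = mad(x, y)
        rows.append({
            "method": est.method_tag, "scale": scale, "cell_type": ct,
            "r": r_val, "mad": mad_val, **(condition or {}),
        })
    if include_all:
        rows.append({
            "method": est.method_tag, "scale": scale, "cell_type": "all",
            "r": float(np.mean([r["r"] for r in rows])),
            "mad": float(np.mean([r["mad"] for r in rows])),
            **(condition or {}),
        })
    return pd.DataFrame(rows)


def ground_truth_scales(
    truth_with_unknown: WeightMatrix, unknown_label: str = "tumor"
) -> tuple[WeightMatrix, WeightMatrix]:
    """Split a truth containing one unknown row into (absolute, relative).

    Absolute keeps the known rows as-is (columns sum to 1 - t_j); relative
    renormalizes them to sum one. With zero unknown content the two coincide.
    """
    if unknown_label not in truth_with_unknown.cell_types:
        raise ValueError(f"unknown row {unknown_label!r} missing from truth")
    known = [ct for ct in truth_with_unknown.cell_types if ct != unknown_label]
    sub = truth_with_unknown.values.loc[known]
    absolute = WeightMatrix(sub, regime="custom", require_sum_to_one=False)
    relative = WeightMatrix(sub / sub.sum(axis=0), regime="custom")
    return absolute, relative


def summarize(results: pd.DataFrame, over: list[str]) -> pd.DataFrame:
    """Arithmetic mean of r and mAD within each group of ``over`` keys.

    Penalized (-1 / 1) entries enter the averages unchanged. Empty result
    sets for a grouping are simply absent (dropped with a warning upstream).
    """
    missing = [k for k in over if k not in results.columns]
    if missing:
        raise ValueError(f"grouping keys not in results: {missing}")
    if results.empty:
        warnings.warn("empty results table", RuntimeWarning)
        return results
    if not over:
        return pd.DataFrame([{"r": results["r"].mean(), "mad": results["mad"].mean()}])
    return (
        results.groupby(over, as_index=False, observed=True)[["r", "mad"]]
        .mean()
    )


def rank_methods(
    summary: pd.DataFrame,
    metric: str = "r",
    condition_keys: list[str] | None = None,
) -> pd.DataFrame:
    """Rank methods per condition: r descending, mAD ascending, average ties."""
    if metric not in ("r", "mad"):
        raise ValueError(f"unknown metric {metric!r}; expected 'r' or 'mad'")
    if metric not in summary.columns or "method" not in summary.columns:
        raise ValueError("summary must contain 'method' and the metric column")
    out = summary.copy()
    ascending = metric == "mad"
    if condition_keys:
        out[f"rank_{metric}"] = out.groupby(condition_keys, observed=True)[metric].rank(
            ascending=ascending, method="average"
        )
    else:
        out[f"rank_{metric}"] = out[metric].rank(ascending=ascending, method="average")
    return out
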