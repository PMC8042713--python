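"""Variance-structure diagnostics for simulation realism.

Three views compare simulated count matrices against what real RNA-seq data
look like:

* mean-variance relation — per-gene moments and the log-log least-squares
  slope: ~1 for pure Poisson counts, drifting towards 2 as gamma
  (biological) overdispersion takes over, since Var ~ mu + mu^2 * sigma^2;
* CV density — per-gene coefficient of variation (sd / mean); its median
  rises with the noise gradient and its density should stay unimodal and
  bell-shaped for a realistic simulator;
* sample-sample concordance — Spearman correlation and Euclidean distance
  for every sample pair.
"""

from __future__ import annotations

import itertools
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .profiles import ExpressionMatrix

__all__ = [
    "mean_variance_table",
    "cv_table",
    "pairwise_sample_stats",
    "count_density_modes",
]


def mean_variance_table(m: ExpressionMatrix) -> tuple[pd.DataFrame, float]:
    """Per-gene (mean, variance) plus the log10-log10 least-squares slope.

    The slope is fit over genes with mean >= 1 and positive variance; it is
    NaN when fewer than two such genes exist (e.g. a constant matrix).
    """
    if m.n_samples < 3:
        raise ValueError("need at least three samples for variance estimates")
    v = m.values.to_numpy()
    mean = v.mean(axis=1)
    var = v.var(axis=1, ddof=1)
    table = pd.DataFrame({"mean": mean, "variance": var}, index=m.gene_ids)
    ok = (mean >= 1.0) & (var > 0)
    if ok.sum() < 2:
        return table, float("nan")
    slope, _ = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), 1)
    return table, float(slope)


def cv_table(m: ExpressionMatrix, grid_points: int = 512) -> tuple[pd.DataFrame, dict]:
    """Per-gene CV (sd / mean) plus density-shape summary.

    All-zero genes are excluded (their CV is undefined); the summary reports
    how many were dropped, the median CV, and the number of local maxima of a
    Gaussian kernel density evaluated on a fixed grid — a testable proxy for
    the "unimodal bell-shaped" density expectation.
    """
    v = m.values.to_numpy()
    mean = v.mean(axis=1)
    keep = mean > 0
    sd = v.std(axis=1, ddof=1)
    cv = sd[keep] / mean[keep]
    table = pd.DataFrame({"cv": cv}, index=m.gene_ids[keep])
    summary = {
        "n_excluded_zero_genes": int((~keep).sum()),
        "median_cv": float(np.median(cv)) if cv.size else float("nan"),
        "n_density_modes": count_density_modes(cv, grid_points=grid_points),
    }
    return table, summary


def count_density_modes(
    x: np.ndarray, grid_points: int = 512, min_prominence: float = 0.05
) -> int:
    """Local maxima of a Gaussian KDE on a fixed grid (<= 1 means unimodal).

    Only peaks with prominence of at least ``min_prominence`` times the
    density maximum count as modes, so numerical ripples in the tails do not
    register.
    """
    from scipy.signal import find_peaks

    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        return 1 if x.size else 0
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), grid_points)
    d = kde(grid)
    # pad with zeros so boundary modes register as peaks
    padded = np.concatenate([[0.0], d, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence * d.max())
    return max(int(peaks.size), 1)


def pairwise_sample_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Spearman correlation and Euclidean distance for all sample pairs.

    Returned long-form with one row per unordered pair; the implied matrices
    are symmetric with unit diagonal (correlation) and zero diagonal
    (distance).
    """
    if m.n_samples < 2:
        raise ValueError("need at least two samples")
    v = m.values.to_numpy()
    rho = stats.spearmanr(v).statistic if m.n_samples > 2 else None
    if m.n_samples == 2:
        r12 = stats.spearmanr(v[:, 0], v[:, 1]).statistic
        rho = np.array([[1.0, r12], [r12, 1.0]])
    dist = squareform(pdist(v.T))
    rows = []
    ids = list(m.sample_ids)
    for i, j in itertools.combinations(range(len(ids)), 2):
        rows.append({
            "sample_a": ids[i], "sample_b": ids[j],
            "spearman_r": float(rho[i, j]), "euclidean_d": float(dist[i, j]),
        })
    return pd.DataFrame(rows)
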