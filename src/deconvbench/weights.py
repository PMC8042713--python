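"""Cell-type proportion (weight) matrix generators and tumor spike-ins.

Four regimes probe how the conditioning of the mixing system affects
deconvolution:

* ``orthog``   — best-conditioned of 1000 random candidates (smallest 2-norm
  condition number): the idealized, nearly orthogonal design.
* ``real``     — proportions sampled inside published whole-blood composition
  ranges, so columns resemble actual blood samples (ill-conditioned: the
  neutrophil fraction dominates every sample).
* ``dominant`` — one major component at 0.9-0.99, the rest tied at
  (1 - p_major)/(K - 1) .. + 0.01.
* ``uniform``  — every component in [1/K, 1/K + 0.04].

All generators rescale each column to sum to one. A tumor spike-in appends an
extra unknown-component row with a fraction drawn from one of three bands
(small 0.2-0.3, large 0.7-0.8, mosaic 0.05-0.95).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightMatrix",
    "SpikeSpec",
    "SPIKE_RANGES",
    "REAL_BLOOD_RANGES",
    "make_orthog",
    "make_real",
    "make_dominant",
    "make_uniform",
    "add_tumor_spikein",
]

REGIMES = ("orthog", "real", "dominant", "uniform", "custom")

#: Tumor-fraction sampling bands per spike-in group.
SPIKE_RANGES = {"small": (0.2, 0.3), "large": (0.7, 0.8), "mosaic": (0.05, 0.95)}

#: Default whole-blood composition ranges (fractions) used by the "real"
#: regime. Approximate literature values for adult peripheral blood; the
#: myeloid DC and CD4 T entries absorb cell types not modeled explicitly.
#: Override per call for other tissues.
REAL_BLOOD_RANGES: dict[str, tuple[float, float]] = {
    "neutrophils": (0.50, 0.70),
    "T": (0.08, 0.31),
    "CD4 T": (0.04, 0.20),
    "CD8 T": (0.04, 0.11),
    "B": (0.02, 0.07),
    "naive B": (0.01, 0.04),
    "memory B": (0.01, 0.03),
    "NK": (0.01, 0.06),
    "monocytes": (0.02, 0.10),
    "eosinophils": (0.00, 0.05),
    "myeloid DC": (0.003, 0.009),
    "HSC": (0.001, 0.01),
}


@dataclass
class WeightMatrix:
    """K x J cell-type proportion matrix with a sum-to-one column contract."""

    values: pd.DataFrame  # cell types x samples
    regime: str = "custom"
    seed: int | None = None
    #: absolute-scale ground truths legitimately sum below one per column
    require_sum_to_one: bool = True

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        v = self.values.to_numpy()
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValueError("weights must lie in [0, 1]")
        if self.require_sum_to_one:
            colsums = v.sum(axis=0)
            if np.abs(colsums - 1.0).max() > 1e-9:
                raise ValueError("weight columns must sum to 1 within 1e-9")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def condition_number(self) -> float:
        """2-norm condition number (largest / smallest singular value)."""
        return float(np.linalg.cond(self.values.to_numpy(), 2))

    def renormalized(self, rows: list[str] | None = None) -> "WeightMatrix":
        """Restrict to ``rows`` and rescale columns back to sum one."""
        sub = self.values if rows is None else self.values.loc[rows]
        return WeightMatrix(sub / sub.sum(axis=0), regime="custom", seed=self.seed)


@dataclass
class SpikeSpec:
    """Tumor spike-in: group names the sampling band for the tumor fraction."""

    group: str = "none"
    tumor_label: str = "tumor"
    mode: str = "final_fraction"
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in (*SPIKE_RANGES, "none"):
            raise ValueError(f"unknown spike group {self.group!r}")
        if self.mode not in ("final_fraction", "append_rescale"):
            raise ValueError(f"unknown spike mode {self.mode!r}")
        if self.range is None and self.group != "none":
            self.range = SPIKE_RANGES[self.group]
        if self.range is not None:
            lo, hi = self.range
            if not 0 <= lo < hi <= 1:
                raise ValueError("spike range must satisfy 0 <= min < max <= 1")


def _sample_ids(J: int) -> list[str]:
    return [f"sample_{j:02d}" for j in range(J)]


def _labels(K: int, cell_types: list[str] | None) -> list[str]:
    if cell_types is not None:
        if len(cell_types) != K:
            raise ValueError("cell_types length must equal K")
        return list(cell_types)
    return [f"ct_{k}" for k in range(K)]


def make_orthog(
    K: int,
    J: int,
    n_candidates: int = 1000,
    seed: int = 0,
    cell_types: list[str] | None = None,
) -> WeightMatrix:
    """Best-conditioned of ``n_candidates`` random column-normalized matrices.

    Candidates are K x J uniform draws with columns rescaled to sum one; the
    returned matrix attains the minimal 2-norm condition number among them
    (ties broken by first index).
    """
    if K < 1:
        raise ValueError("K must be positive")
    if J < K:
        raise ValueError("J must be >= K (condition number degenerate otherwise)")
    rng = np.random.default_rng(seed)
    best, best_cond = None, np.inf
    for _ in range(n_candidates):
        w = rng.uniform(size=(K, J))
        w /= w.sum(axis=0)
        c = np.linalg.cond(w, 2)
        if c < best_cond:
            best, best_cond = w, c
    df = pd.DataFrame(best, index=_labels(K, cell_types), columns=_sample_ids(J))
    return WeightMatrix(df, regime="orthog", seed=seed)


def orthog_candidates(
    K: int, J: int, n_candidates: int = 1000, seed: int = 0
) -> list[np.ndarray]:
    """Replay the exact candidate set scanned by :func:`make_orthog`."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_candidates):
        w = rng.uniform(size=(K, J))
        out.append(w / w.sum(axis=0))
    return out


def make_real(
    K: int,
    J: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_candidates: int = 1000,
    seed: int = 0,
    cell_types: list[str] | None = None,
    max_rounds: int = 100,
) -> WeightMatrix:
    """Blood-like proportions sampled inside per-cell-type composition ranges.

    ``n_candidates`` column vectors are drawn with each component uniform in
    its [min, max]; the J columns whose raw sums are closest to one are kept
    and rescaled. Columns whose rescaled entries escape their range are
    resampled until all J satisfy both the sum-to-one and range constraints.
    """
    labels = _labels(K, cell_types)
    if ranges is None:
        try:
            ranges = {ct: REAL_BLOOD_RANGES[ct] for ct in labels}
        except KeyError as e:
            raise ValueError(
                f"no default blood range for cell type {e.args[0]!r}; pass ranges"
            ) from None
    lo = np.array([ranges[ct][0] for ct in labels])
    hi = np.array([ranges[ct][1] for ct in labels])
    if (lo > hi).any() or (lo < 0).any() or (hi > 1).any():
        raise ValueError("each range must satisfy 0 <= min <= max <= 1")
    if lo.sum() > 1 + 1e-12 or hi.sum() < 1 - 1e-12:
        raise ValueError(
            f"ranges cannot sum to 1 (min-sum {lo.sum():.3f}, max-sum {hi.sum():.3f})"
        )

    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    for _ in range(max_rounds):
        cand = rng.uniform(lo[:, None], hi[:, None], size=(K, n_candidates))
        sums = cand.sum(axis=0)
        order = np.argsort(np.abs(sums - 1.0), kind="stable")
        for idx in order:
            col = cand[:, idx] / sums[idx]
            # tolerance absorbs float noise on degenerate (min == max) ranges
            if ((col >= lo - 1e-12) & (col <= hi + 1e-12)).all():
                accepted.append(col)
                if len(accepted) == J:
                    break
        if len(accepted) == J:
            break
    else:
        raise RuntimeError("could not satisfy range constraints after resampling")
    df = pd.DataFrame(np.column_stack(accepted), index=labels, columns=_sample_ids(J))
    return WeightMatrix(df, regime="real", seed=seed)


def make_dominant(
    K: int,
    J: int,
    seed: int = 0,
    major_type: str | None = None,
    cell_types: list[str] | None = None,
) -> WeightMatrix:
    """One major component at U(0.9, 0.99); minors in a narrow tied band."""
    if K < 2:
        raise ValueError("dominant regime needs at least 2 components")
    labels = _labels(K, cell_types)
    major_idx = 0 if major_type is None else labels.index(major_type)
    rng = np.random.default_rng(seed)
    w = np.empty((K, J))
    for j in range(J):
        p_major = rng.uniform(0.9, 0.99)
        band_lo = (1.0 - p_major) / (K - 1)
        minors = rng.uniform(band_lo, band_lo + 0.01, size=K - 1)
        col = np.insert(minors, major_idx, p_major)
        w[:, j] = col / col.sum()
    df = pd.DataFrame(w, index=labels, columns=_sample_ids(J))
    return WeightMatrix(df, regime="dominant", seed=seed)


def make_uniform(
    K: int,
    J: int,
    seed: int = 0,
    cell_types: list[str] | None = None,
) -> WeightMatrix:
    """All components at a similar level: U(1/K, 1/K + 0.04) then rescaled."""
    if K < 1:
        raise ValueError("K must be positive")
    rng = np.random.default_rng(seed)
    w = rng.uniform(1.0 / K, 1.0 / K + 0.04, size=(K, J))
    w /= w.sum(axis=0)
    df = pd.DataFrame(w, index=_labels(K, cell_types), columns=_sample_ids(J))
    return WeightMatrix(df, regime="uniform", seed=seed)


def add_tumor_spikein(w: WeightMatrix, spec: SpikeSpec, seed: int = 0) -> WeightMatrix:
    """Append an unknown tumor row with per-sample fractions from spec.range.

    ``final_fraction`` scales the existing column by (1 - t) so the tumor
    fraction of the final mixture lands exactly in the advertised band;
    ``append_rescale`` appends t and divides by (1 + t). Either way columns
    sum to one, and the renormalized known-cell-type proportions are
    unchanged. ``group='none'`` passes through with a zero tumor row.
    """
    if spec.tumor_label in w.cell_types:
        raise ValueError(f"tumor label {spec.tumor_label!r} already present")
    J = w.n_samples
    if spec.group == "none":
        t = np.zeros(J)
    else:
        rng = np.random.default_rng(seed)
        t = rng.uniform(*spec.range, size=J)
    v = w.values.to_numpy()
    if spec.mode == "final_fraction":
        new = np.vstack([v * (1.0 - t), t])
    else:  # append_rescale
        new = np.vstack([v, t]) / (1.0 + t)
    df = pd.DataFrame(
        new, index=[*w.cell_types, spec.tumor_label], columns=w.values.columns
    )
    return WeightMatrix(df, regime="custom", seed=seed)
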