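"""Built-in deconvolution baseline and the external-estimate adapter.

The baseline solves, per mixture sample, a non-negative least squares fit of
the (library-size normalized) mixture against the reference cell-type
profiles restricted to a gene list, then rescales the coefficients to sum to
one. It exists to exercise the harness end-to-end; published methods are
consumed through :func:`read_estimates`, which parses their cell-type x
sample proportion tables (NA cells allowed — they are penalized downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .profiles import ExpressionMatrix

__all__ = ["ProportionEstimate", "nnls_deconvolve", "read_estimates"]


@dataclass
class ProportionEstimate:
    """Cell-type x sample proportion estimates from one method."""

    values: pd.DataFrame
    method_tag: str = "unknown"
    scale_claim: str = "relative"  # relative | absolute | unnormalized
    na_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale_claim not in ("relative", "absolute", "unnormalized"):
            raise ValueError(f"unknown scale_claim {self.scale_claim!r}")
        if self.na_mask is None:
            self.na_mask = self.values.isna()
        v = self.values.to_numpy()
        if (v[~self.na_mask.to_numpy()] < 0).any():
            raise ValueError("proportion estimates must be non-negative")
        if self.scale_claim == "relative":
            sums = self.values.where(~self.na_mask).sum(axis=0, skipna=True)
            full = ~self.na_mask.any(axis=0)
            if full.any() and (np.abs(sums[full] - 1.0) > 1e-6).any():
                raise ValueError("relative estimates must have columns summing to 1")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)


def _cpm(values: pd.DataFrame) -> pd.DataFrame:
    lib = values.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size column")
    return values / lib * 1e6


def nnls_deconvolve(
    mixture: ExpressionMatrix,
    reference: ExpressionMatrix,
    genes: list[str] | None = None,
    method_tag: str = "builtin_nnls",
) -> ProportionEstimate:
    """Non-negative least squares baseline.

    Both inputs are internally normalized to counts-per-million before
    fitting (so count and cpm inputs of the same fixed-library mixture give
    identical estimates), restricted to ``genes`` (default: the shared gene
    set), solved per sample without a sum constraint, then rescaled to sum
    one. An all-zero solution for a sample yields NA estimates there.
    """
    if reference.n_samples < 2:
        raise ValueError("reference must contain at least two cell types")
    shared = mixture.gene_ids.intersection(reference.gene_ids)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) == 0:
        raise ValueError("empty gene intersection between mixture, reference and gene list")

    R = _cpm(reference.values).loc[shared].to_numpy()
    M = _cpm(mixture.values).loc[shared].to_numpy()
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"reference matrix is near-singular (condition number {cond:.3g})",
            RuntimeWarning,
        )

    K, J = reference.n_samples, mixture.n_samples
    out = np.empty((K, J))
    for j in range(J):
        coef, _ = nnls(R, M[:, j])
        s = coef.sum()
        out[:, j] = coef / s if s > 0 else np.nan
    df = pd.DataFrame(out, index=reference.sample_ids, columns=mixture.sample_ids)
    return ProportionEstimate(df, method_tag=method_tag, scale_claim="relative")


def read_estimates(
    path: str | Path,
    method_tag: str,
    expected_cell_types: list[str] | None = None,
    scale_claim: str = "unnormalized",
) -> ProportionEstimate:
    """Read a cell-type x sample proportion TSV; blank/NA cells allowed.

    When ``expected_cell_types`` is given, the file's roster must match it
    exactly; mismatches raise with the symmetric difference listed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if expected_cell_types is not None:
        have, want = set(df.index), set(expected_cell_types)
        if have != want:
            raise ValueError(
                "cell-type roster mismatch: "
                f"extra={sorted(have - want)}, missing={sorted(want - have)}"
            )
        df = df.loc[expected_cell_types]
    return ProportionEstimate(df, method_tag=method_tag, scale_claim=scale_claim)
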