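"""Noise models for in-silico mixture simulation.

Three sample-to-sample variability models are provided, each driven by a
10-step perturbation gradient ``p_t``:

* normal:     M = 2 ** (log2(X + 1) + N(0, sigma * p_t))
* log-normal: M = X + 2 ** N(0, sigma * p_t)
* negative binomial (gamma-Poisson):
      mu_i0   = r_i0 * L_j
      sigma_i = (1.8 * p_t + 1 / sqrt(mu_i0)) * exp(delta / 2),  delta ~ N(0, sd 0.5)
      mu_ij   ~ Gamma(shape = 1 / sigma_i**2, scale = mu_i0 * sigma_i**2)
      v_ij    ~ Poisson(mu_ij)

The gamma layer models biological variance (per-gene dispersion, drawn once
per gene), the Poisson layer technical counting variance; the library size
``L_j`` fixes the expected per-sample total counts because the feature
proportions r sum to one. sigma defaults to 10 for the normal/log-normal
models. The grids are {0, 0.1, ..., 0.9} for normal/log-normal and
{0.1, ..., 1.0} for the negative binomial model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "NORMAL_PT_GRID",
    "NB_PT_GRID",
    "NoiseSpec",
    "perturb_normal",
    "perturb_lognormal",
    "simulate_nb_counts",
]

#: Perturbation grids: normal/log-normal start at zero noise, nb cannot
#: (its dispersion term never vanishes), so its grid is shifted by one step.
NORMAL_PT_GRID = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9
NB_PT_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))  # 0.1 .. 1.0

MODELS = ("normal", "lognormal", "nb")


@dataclass
class NoiseSpec:
    """Parameters of one noise configuration.

    Attributes
    ----------
    model
        ``normal``, ``lognormal`` or ``nb``.
    p_t
        Perturbation level in [0, 1].
    sigma
        Constant noise multiplier for the normal/log-normal models.
    library_size
        Reads per sample (nb model only). Either a scalar applied to every
        sample or a per-sample sequence.
    seed
        Seed for the random stream; identical specs give identical draws.
    normal_scale
        Whether the second argument of the normal draws is read as a standard
        deviation (``sd``, default) or a variance (``var``).
    delta_sd
        Standard deviation of the per-gene log-dispersion jitter delta.
    """

    model: str = "nb"
    p_t: float = 0.1
    sigma: float = 10.0
    library_size: float | tuple[float, ...] = 12_000_000
    seed: int = 0
    normal_scale: str = "sd"
    delta_sd: float = 0.5
    delta_per_sample: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.p_t <= 1.0:
            raise ValueError("p_t must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.normal_scale not in ("sd", "var"):
            raise ValueError("normal_scale must be 'sd' or 'var'")
        lib = np.atleast_1d(np.asarray(self.library_size, dtype=float))
        if (lib < 1e4).any():
            raise ValueError("library_size must be at least 1e4 reads")

    def noise_sd(self) -> float:
        """Scale of the N(0, sigma * p_t) term under the configured convention."""
        s = self.sigma * self.p_t
        return s if self.normal_scale == "sd" else float(np.sqrt(s))

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["library_size"], tuple):
            d["library_size"] = list(d["library_size"])
        return d


def _check_expected(expected: np.ndarray) -> np.ndarray:
    x = np.asarray(expected, dtype=float)
    if (x < 0).any():
        raise ValueError("expected expression must be non-negative")
    return x


def perturb_normal(expected: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Multiplicative log-space noise: 2 ** (log2(x + 1) + N(0, sigma * p_t)).

    At p_t = 0 the output is exactly x + 1 (the +1 pseudocount is part of the
    model); outputs are strictly positive for any input.
    """
    if spec.model != "normal":
        raise ValueError(f"spec.model is {spec.model!r}, expected 'normal'")
    x = _check_expected(expected)
    rng = np.random.default_rng(spec.seed)
    z = rng.normal(0.0, spec.noise_sd(), size=x.shape) if spec.p_t > 0 else 0.0
    return np.exp2(np.log2(x + 1.0) + z)


def perturb_lognormal(expected: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Additive positive noise: x + 2 ** N(0, sigma * p_t).

    The added term has median 1 (the exponent is symmetric about 0), so the
    zero-noise limit is x + 1 and every output strictly exceeds the input.
    """
    if spec.model != "lognormal":
        raise ValueError(f"spec.model is {spec.model!r}, expected 'lognormal'")
    x = _check_expected(expected)
    rng = np.random.default_rng(spec.seed)
    z = rng.normal(0.0, spec.noise_sd(), size=x.shape) if spec.p_t > 0 else np.zeros(x.shape)
    return x + np.exp2(z)


def simulate_nb_counts(
    feature_props: np.ndarray,
    spec: NoiseSpec,
    n_samples: int,
    rng: np.random.Generator | None = None,
    delta: np.ndarray | None = None,
) -> np.ndarray:
    """Gamma-Poisson count simulation for one expression profile.

    ``feature_props`` is the expected genomic feature proportion of each gene
    (a simplex vector r); with library size L the expected count of gene i is
    mu_i0 = r_i * L, so expected per-sample totals equal L exactly. The
    per-gene dispersion jitter delta is drawn once per gene by default
    (dispersion is a gene property); pass ``delta`` to pin it, e.g. zeros for
    variance-formula checks.

    Returns an integer matrix of shape (n_genes, n_samples).
    """
    if spec.model != "nb":
        raise ValueError(f"spec.model is {spec.model!r}, expected 'nb'")
    r = np.asarray(feature_props, dtype=float)
    if r.ndim != 1:
        raise ValueError("feature_props must be a vector")
    if (r < 0).any():
        raise ValueError("feature proportions must be non-negative")
    if abs(r.sum() - 1.0) > 1e-8:
        raise ValueError(f"feature proportions must sum to 1 (got {r.sum()!r})")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_genes = r.size
    lib = np.asarray(spec.library_size, dtype=float)
    if lib.ndim == 0:
        lib = np.full(n_samples, float(lib))
    elif lib.size != n_samples:
        raise ValueError(f"library_size has {lib.size} entries for {n_samples} samples")

    mu0 = r[:, None] * lib[None, :]  # n_genes x n_samples expected counts
    pos = r > 0

    if delta is None:
        shape_d = (n_genes, n_samples) if spec.delta_per_sample else (n_genes,)
        delta = rng.normal(0.0, spec.delta_sd, size=shape_d)
    delta = np.asarray(delta, dtype=float)
    if delta.ndim == 1:
        delta = delta[:, None]
    delta = np.broadcast_to(delta, (n_genes, n_samples))

    counts = np.zeros((n_genes, n_samples), dtype=np.int64)
    if pos.any():
        mu0_p = mu0[pos, :]
        # sigma_i > 0 always: the 1/sqrt(mu0) floor never vanishes for finite
        # means, so the gamma shape 1/sigma^2 is finite.
        sig = (1.8 * spec.p_t + 1.0 / np.sqrt(mu0_p)) * np.exp(delta[pos, :] / 2.0)
        gshape = 1.0 / sig**2
        mu = rng.gamma(gshape, mu0_p / gshape)
        counts[pos, :] = rng.poisson(mu)
    return counts
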