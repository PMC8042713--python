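"""Mixture assembly (M = S x W + noise) and benchmark scenario builders.

Three scenario families mirror the benchmarking designs:

* ``sim1_simModel`` — three noise models across a 10-step gradient, three
  independent source datasets, all 3 x 3 mixture-reference pairings per level.
* ``sim1_libSize``  — negative-binomial mixtures with a two-group library-size
  split (samples 1-10 at 12 M reads, 11-20 at 24 M), emitted in all four
  quantification units.
* ``sim2`` / ``sim3`` — component-number gradient (5-10 cell types, roster
  below) under chosen weight regimes at low nb noise; sim3 re-mixes each
  sim2 set in count space with a tumor spike-in and carries dual (absolute
  and relative) ground truths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .noise import NB_PT_GRID, NORMAL_PT_GRID, NoiseSpec, perturb_lognormal, perturb_normal, simulate_nb_counts
from .profiles import ExpressionMatrix, SourceProfiles, build_reference, convert_units, generate_source_profiles
from .weights import SpikeSpec, WeightMatrix, add_tumor_spikein, make_dominant, make_orthog, make_real, make_uniform

__all__ = [
    "COMPONENT_ROSTERS",
    "MixtureSet",
    "Scenario",
    "mix_expected",
    "apply_noise",
    "build_sim1",
    "build_sim1_libsize",
    "build_sim2",
    "build_sim3",
]

#: Cell-type rosters for the component-number gradient (Comp 5 .. Comp 10).
#: Comp 9 splits T into CD4/CD8; Comp 10 additionally splits B into
#: naive/memory.
COMPONENT_ROSTERS: dict[int, tuple[str, ...]] = {
    5: ("T", "B", "monocytes", "neutrophils", "NK"),
    6: ("T", "B", "monocytes", "neutrophils", "NK", "eosinophils"),
    7: ("T", "B", "monocytes", "neutrophils", "NK", "eosinophils", "myeloid DC"),
    8: ("T", "B", "monocytes", "neutrophils", "NK", "eosinophils", "myeloid DC", "HSC"),
    9: (
        "CD4 T", "CD8 T", "B", "monocytes", "neutrophils", "NK",
        "eosinophils", "myeloid DC", "HSC",
    ),
    10: (
        "CD4 T", "CD8 T", "naive B", "memory B", "monocytes", "neutrophils",
        "NK", "eosinophils", "myeloid DC", "HSC",
    ),
}


@dataclass
class MixtureSet:
    """A simulated mixture with its ground truths and provenance."""

    mixture: ExpressionMatrix
    truth_absolute: WeightMatrix  # includes the unknown row when present
    truth_relative: WeightMatrix  # known cell types only, columns sum to 1
    noise: NoiseSpec
    scenario_tag: str = "custom"
    source_tag: str = "synthetic"
    unknown_label: str | None = None
    spike_group: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mixture.n_samples != self.truth_relative.n_samples:
            raise ValueError("mixture and truth sample counts differ")

    @property
    def known_cell_types(self) -> list[str]:
        return self.truth_relative.cell_types


@dataclass
class Scenario:
    """Configuration for the scenario builders (paper-mode defaults)."""

    models: tuple[str, ...] = ("normal", "lognormal", "nb")
    p_t_grid: tuple[float, ...] | None = None  # default: model-specific grid
    component_gradient: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    regimes: tuple[str, ...] = ("orthog", "real")
    spike_groups: tuple[str, ...] = ("small", "large", "mosaic")
    units: tuple[str, ...] = ("count",)
    n_source_datasets: int = 3
    n_samples: int = 20
    n_genes: int = 2000
    n_replicates: int = 5
    library_size: float = 12_000_000
    nb_low_pt: float = 0.1  # "close to p_1 level"
    sigma: float = 10.0

    def grid_for(self, model: str) -> tuple[float, ...]:
        if self.p_t_grid is not None:
            return self.p_t_grid
        return NB_PT_GRID if model == "nb" else NORMAL_PT_GRID


def _stream_seed(seed: int, *labels) -> int:
    """Stable named-stream seed derivation, independent across labels."""
    import hashlib

    h = hashlib.blake2b(
        ("/".join(str(x) for x in (seed, *labels))).encode(), digest_size=4
    )
    return int.from_bytes(h.digest(), "little") % (2**31)


def mix_expected(src: SourceProfiles, w: WeightMatrix) -> pd.DataFrame:
    """Expected noise-free mixture S x W (genes x samples)."""
    missing = [ct for ct in w.cell_types if ct not in src.cell_types]
    if missing:
        raise ValueError(f"weight cell types absent from source: {missing}")
    S = src.mean_profiles[w.cell_types].to_numpy()
    M = S @ w.values.to_numpy()
    return pd.DataFrame(M, index=src.gene_ids, columns=w.values.columns)


def apply_noise(
    expected: pd.DataFrame,
    spec: NoiseSpec,
    mode: str = "mixture_level",
    w: WeightMatrix | None = None,
    src: SourceProfiles | None = None,
    round_counts: bool = True,
) -> ExpressionMatrix:
    """Realize a noisy mixture from its expected profile.

    ``mixture_level`` applies the noise model to the expected mixture S x W
    per sample (for nb, the per-sample feature proportions come from
    normalizing the expected mixture profile). ``component_level`` (nb only)
    simulates an independent count realization per cellular component at the
    full library size and sums them weighted by w: the expected per-sample
    total is then sum_k w_kj * L = L. Component sums are real-valued unless
    ``round_counts``.
    """
    lengths = None if src is None else src.gene_lengths
    if spec.model in ("normal", "lognormal"):
        if mode != "mixture_level":
            raise ValueError(f"mode {mode!r} is nb-only")
        fn = perturb_normal if spec.model == "normal" else perturb_lognormal
        out = fn(expected.to_numpy(), spec)
        df = pd.DataFrame(out, index=expected.index, columns=expected.columns)
        return ExpressionMatrix(df, unit="count", gene_lengths=lengths)

    rng = np.random.default_rng(spec.seed)
    n_genes, n_samples = expected.shape
    if mode == "mixture_level":
        counts = np.empty((n_genes, n_samples), dtype=np.int64)
        r = expected.to_numpy() / expected.to_numpy().sum(axis=0, keepdims=True)
        # dispersion jitter is a gene property: draw once, share across samples
        delta = None
        if not spec.delta_per_sample:
            delta = rng.normal(0.0, spec.delta_sd, size=n_genes)
        lib = np.asarray(spec.library_size, dtype=float)
        for j in range(n_samples):
            lib_j = float(lib) if lib.ndim == 0 else float(lib[j])
            sub = NoiseSpec(**{**spec.to_dict(), "library_size": lib_j})
            counts[:, j] = simulate_nb_counts(r[:, j], sub, 1, rng=rng, delta=delta)[:, 0]
        out = counts.astype(float)
    elif mode == "component_level":
        if w is None or src is None:
            raise ValueError("component_level needs the weight matrix and source")
        out = np.zeros((n_genes, n_samples))
        for ct in w.cell_types:
            prof = src.mean_profiles[ct].to_numpy()
            r = prof / prof.sum()
            v = simulate_nb_counts(r, spec, n_samples, rng=rng)
            out += v * w.values.loc[ct].to_numpy()[None, :]
        if round_counts:
            out = np.rint(out)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.DataFrame(out, index=expected.index, columns=expected.columns)
    return ExpressionMatrix(df, unit="count", gene_lengths=lengths)


def _identity_truths(w: WeightMatrix) -> tuple[WeightMatrix, WeightMatrix]:
    return w, w


def build_sim1(
    scenario: Scenario | None = None,
    seed: int = 0,
    mode: str = "component_level",
) -> list[dict]:
    """Noise-model x gradient design with replicated mixture-reference pairs.

    For each model and each noise level, ``n_source_datasets`` independent
    synthetic sources each yield one mixture set and one reference; all
    source x source pairings are enumerated (9 testing environments per level
    in the default 3-source design, 6 of them cross-source).

    Returns a list of dicts with keys ``mixture_set``, ``reference``,
    ``mixture_source``, ``reference_source``, ``model``, ``p_t``.
    """
    sc = scenario or Scenario()
    cell_types = ["T", "B", "monocytes"]
    sources, references = {}, {}
    for d in range(sc.n_source_datasets):
        tag = f"src{d}"
        sources[tag] = generate_source_profiles(
            sc.n_genes, cell_types, n_replicates=sc.n_replicates,
            seed=_stream_seed(seed, "sim1", "source", d), dataset_tag=tag,
        )
        references[tag] = build_reference(sources[tag], cell_types)

    pairs: list[dict] = []
    for model in sc.models:
        for p_t in sc.grid_for(model):
            mixtures = {}
            for tag, src in sources.items():
                w = make_orthog(
                    len(cell_types), sc.n_samples, cell_types=cell_types,
                    seed=_stream_seed(seed, "sim1", "weights", tag, model, p_t),
                )
                spec = NoiseSpec(
                    model=model, p_t=p_t, sigma=sc.sigma,
                    library_size=sc.library_size,
                    seed=_stream_seed(seed, "sim1", "noise", tag, model, p_t),
                )
                expected = mix_expected(src, w)
                nm = "component_level" if (model == "nb" and mode == "component_level") else "mixture_level"
                mix = apply_noise(expected, spec, mode=nm, w=w, src=src)
                mixtures[tag] = MixtureSet(
                    mixture=mix, truth_absolute=w, truth_relative=w, noise=spec,
                    scenario_tag="sim1_simModel", source_tag=tag, seed=seed,
                )
            for mtag in sources:
                for rtag in sources:
                    pairs.append({
                        "mixture_set": mixtures[mtag],
                        "reference": references[rtag],
                        "mixture_source": mtag,
                        "reference_source": rtag,
                        "model": model,
                        "p_t": p_t,
                    })
    return pairs


def build_sim1_libsize(
    scenario: Scenario | None = None,
    seed: int = 0,
    mode: str = "component_level",
) -> list[MixtureSet]:
    """Two-group library-size design: 12 M reads (first half) vs 24 M (second).

    Negative-binomial mixtures only, one set per noise level, each emitted in
    every requested quantification unit.
    """
    sc = scenario or Scenario(units=("count", "countNorm", "cpm", "tpm"))
    if sc.n_samples % 2:
        raise ValueError("the two-group design needs an even sample count")
    half = sc.n_samples // 2
    lib = tuple([12_000_000.0] * half + [24_000_000.0] * half)
    cell_types = ["T", "B", "monocytes"]
    src = generate_source_profiles(
        sc.n_genes, cell_types, n_replicates=sc.n_replicates,
        seed=_stream_seed(seed, "sim1_libsize", "source"), dataset_tag="src0",
    )
    out: list[MixtureSet] = []
    for p_t in sc.grid_for("nb"):
        w = make_orthog(
            len(cell_types), sc.n_samples, cell_types=cell_types,
            seed=_stream_seed(seed, "sim1_libsize", "weights", p_t),
        )
        spec = NoiseSpec(
            model="nb", p_t=p_t, library_size=lib,
            seed=_stream_seed(seed, "sim1_libsize", "noise", p_t),
        )
        expected = mix_expected(src, w)
        mix = apply_noise(expected, spec, mode=mode, w=w, src=src)
        for unit in sc.units:
            out.append(MixtureSet(
                mixture=convert_units(mix, unit),
                truth_absolute=w, truth_relative=w, noise=spec,
                scenario_tag="sim1_libSize", source_tag="src0", seed=seed,
            ))
    return out


_WEIGHT_MAKERS = {
    "orthog": lambda K, J, cts, s: make_orthog(K, J, cell_types=cts, seed=s),
    "real": lambda K, J, cts, s: make_real(K, J, cell_types=cts, seed=s),
    "dominant": lambda K, J, cts, s: make_dominant(K, J, cell_types=cts, seed=s),
    "uniform": lambda K, J, cts, s: make_uniform(K, J, cell_types=cts, seed=s),
}


def build_sim2(
    scenario: Scenario | None = None,
    seed: int = 0,
    source: SourceProfiles | None = None,
    mode: str = "component_level",
) -> list[MixtureSet]:
    """Component-gradient design: one nb mixture set per (K, regime) pair.

    Cell-type rosters follow :data:`COMPONENT_ROSTERS`; noise sits at the low
    end of the nb gradient ("close to p_1", default p_t = 0.1).
    """
    sc = scenario or Scenario()
    all_types = sorted({ct for K in sc.component_gradient for ct in COMPONENT_ROSTERS[K]})
    if source is None:
        source = generate_source_profiles(
            sc.n_genes, all_types, n_replicates=sc.n_replicates,
            seed=_stream_seed(seed, "sim2", "source"), dataset_tag="sim2src",
        )
    missing = [ct for ct in all_types if ct not in source.cell_types]
    if missing:
        raise ValueError(f"source roster missing cell types: {missing}")

    out: list[MixtureSet] = []
    for K in sc.component_gradient:
        roster = list(COMPONENT_ROSTERS[K])
        for regime in sc.regimes:
            w = _WEIGHT_MAKERS[regime](
                K, sc.n_samples, roster, _stream_seed(seed, "sim2", "w", K, regime)
            )
            spec = NoiseSpec(
                model="nb", p_t=sc.nb_low_pt, library_size=sc.library_size,
                seed=_stream_seed(seed, "sim2", "noise", K, regime),
            )
            expected = mix_expected(source, w)
            mix = apply_noise(expected, spec, mode=mode, w=w, src=source)
            out.append(MixtureSet(
                mixture=mix, truth_absolute=w, truth_relative=w, noise=spec,
                scenario_tag="sim2", source_tag=source.dataset_tag, seed=seed,
            ))
    return out


def build_sim3(
    sim2_sets: list[MixtureSet],
    tumor_src: SourceProfiles,
    spike_groups: tuple[str, ...] = ("small", "large", "mosaic"),
    seed: int = 0,
    units: tuple[str, ...] = ("count",),
    tumor_label: str = "tumor",
    mode: str = "component_level",
    spike_mode: str = "final_fraction",
    source: SourceProfiles | None = None,
) -> list[MixtureSet]:
    """Tumor spike-in design: re-mix each input set with an unknown component.

    Each sim2 mixture set is re-simulated in count space with its weight
    matrix augmented by a tumor fraction from the requested band, then
    converted to every requested unit. Ground truths come in two scales:
    absolute (immune proportions of the whole mixture, tumor row included in
    the stored matrix) and relative (immune proportions renormalized over
    known cell types — identical to the pre-spike truth).
    """
    if tumor_label in {ct for ms in sim2_sets for ct in ms.known_cell_types}:
        raise ValueError("tumor source must be distinct from immune cell types")
    out: list[MixtureSet] = []
    for i, ms in enumerate(sim2_sets):
        src = source
        if src is None:
            raise ValueError("pass the immune source used to build the sim2 sets")
        combined = _merge_sources(src, tumor_src, tumor_label)
        for group in spike_groups:
            sspec = SpikeSpec(group=group, tumor_label=tumor_label, mode=spike_mode)
            w_spiked = add_tumor_spikein(
                ms.truth_absolute, sspec, seed=_stream_seed(seed, "sim3", "spike", i, group)
            )
            nspec = NoiseSpec(**{
                **ms.noise.to_dict(),
                "seed": _stream_seed(seed, "sim3", "noise", i, group),
            })
            expected = mix_expected(combined, w_spiked)
            mix = apply_noise(expected, nspec, mode=mode, w=w_spiked, src=combined)
            for unit in units:
                out.append(MixtureSet(
                    mixture=convert_units(mix, unit),
                    truth_absolute=w_spiked,
                    truth_relative=ms.truth_relative,
                    noise=nspec,
                    scenario_tag="sim3",
                    source_tag=ms.source_tag,
                    unknown_label=tumor_label,
                    spike_group=group,
                    seed=seed,
                ))
    return out


def _merge_sources(
    immune: SourceProfiles, tumor: SourceProfiles, tumor_label: str
) -> SourceProfiles:
    """Join immune and tumor sources on their shared gene set."""
    genes = immune.gene_ids.intersection(tumor.gene_ids)
    if len(genes) == 0:
        raise ValueError("immune and tumor sources share no genes")
    tumor_ct = tumor.cell_types[0]
    mean = immune.mean_profiles.loc[genes].copy()
    mean[tumor_label] = tumor.mean_profiles.loc[genes, tumor_ct]
    reps = {ct: m.subset_genes(genes) for ct, m in immune.replicates.items()}
    reps[tumor_label] = tumor.replicates[tumor_ct].subset_genes(genes)
    lengths = None if immune.gene_lengths is None else immune.gene_lengths.loc[genes]
    return SourceProfiles(
        mean_profiles=mean, replicates=reps,
        dataset_tag=f"{immune.dataset_tag}+{tumor.dataset_tag}",
        gene_lengths=lengths,
        marker_genes=immune.marker_genes,
    )
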