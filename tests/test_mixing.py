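"""Mixture assembly and the Sim1/Sim2/Sim3 scenario builders."""

import numpy as np
import pandas as pd
import pytest

from deconvbench import (
    COMPONENT_ROSTERS,
    NoiseSpec,
    Scenario,
    apply_noise,
    build_reference,
    build_sim1,
    build_sim1_libsize,
    build_sim2,
    build_sim3,
    convert_units,
    generate_source_profiles,
    make_uniform,
    mix_expected,
    nnls_deconvolve,
    simulate_nb_counts,
)
from deconvbench.mixing import _stream_seed
from deconvbench.weights import WeightMatrix


SMALL = Scenario(n_genes=400, n_samples=6, n_replicates=3)


class TestMixExpected:
    def test_single_component_identity(self, small_source):
        w = WeightMatrix(pd.DataFrame({"s0": [1.0]}, index=["T"]))
        m = mix_expected(small_source, w)
        np.testing.assert_allclose(m["s0"], small_source.mean_profiles["T"])

    def test_convexity_with_identical_profiles(self, small_source):
        src = small_source
        dup = src.mean_profiles.copy()
        dup["B"] = dup["T"]
        src2 = type(src)(mean_profiles=dup, replicates=src.replicates,
                         dataset_tag="dup", gene_lengths=src.gene_lengths)
        w = WeightMatrix(pd.DataFrame({"s0": [0.5, 0.5]}, index=["T", "B"]))
        m = mix_expected(src2, w)
        np.testing.assert_allclose(m["s0"], dup["T"])

    def test_marker_linearity(self, small_source):
        marker = small_source.marker_genes["T"][0]
        w = WeightMatrix(pd.DataFrame({"s0": [0.3, 0.7]}, index=["T", "B"]))
        m = mix_expected(small_source, w)
        expected = (0.3 * small_source.mean_profiles.loc[marker, "T"]
                    + 0.7 * small_source.mean_profiles.loc[marker, "B"])
        assert m.loc[marker, "s0"] == pytest.approx(expected)

    def test_unknown_cell_type_rejected(self, small_source):
        w = WeightMatrix(pd.DataFrame({"s0": [1.0]}, index=["nope"]))
        with pytest.raises(ValueError, match="absent"):
            mix_expected(small_source, w)


class TestApplyNoise:
    def test_normal_zero_noise_is_expected_plus_one(self, small_source):
        w = make_uniform(3, 4, seed=0, cell_types=small_source.cell_types)
        expected = mix_expected(small_source, w)
        spec = NoiseSpec(model="normal", p_t=0.0, seed=1)
        out = apply_noise(expected, spec)
        np.testing.assert_allclose(out.values.to_numpy(), expected.to_numpy() + 1.0)

    def test_component_level_degenerate_weights_match_single_component(self, small_source):
        # weights (1, 0) reproduce the single-component count distribution
        w = WeightMatrix(pd.DataFrame({"s0": [1.0, 0.0], "s1": [1.0, 0.0]},
                                      index=["T", "B"]))
        expected = mix_expected(small_source, w)
        spec = NoiseSpec(model="nb", p_t=0.2, library_size=1e6, seed=2)
        out = apply_noise(expected, spec, mode="component_level",
                          w=w, src=small_source)
        prof = small_source.mean_profiles["T"].to_numpy()
        rng = np.random.default_rng(2)
        direct = simulate_nb_counts(prof / prof.sum(), spec, 2, rng=rng)
        np.testing.assert_array_equal(out.values.to_numpy(), direct)

    def test_mixture_level_library_size_within_one_percent(self, small_source):
        src = generate_source_profiles(10_000, ["T", "B"], seed=5)
        w = make_uniform(2, 20, seed=5, cell_types=["T", "B"])
        expected = mix_expected(src, w)
        spec = NoiseSpec(model="nb", p_t=0.1, library_size=12e6, seed=6)
        out = apply_noise(expected, spec, mode="mixture_level")
        assert out.values.sum(axis=0).mean() == pytest.approx(12e6, rel=0.01)

    def test_component_level_requires_nb(self, small_source):
        w = make_uniform(3, 2, seed=0, cell_types=small_source.cell_types)
        expected = mix_expected(small_source, w)
        with pytest.raises(ValueError):
            apply_noise(expected, NoiseSpec(model="normal", p_t=0.1),
                        mode="component_level", w=w, src=small_source)


class TestBuildSim1:
    def test_pairing_enumeration_counts(self):
        sc = Scenario(models=("nb",), n_genes=300, n_samples=4, n_replicates=3)
        pairs = build_sim1(sc, seed=1)
        # 1 model x 10 levels x (3 x 3) pairings
        assert len(pairs) == 90
        by_level = {}
        for p in pairs:
            by_level.setdefault(p["p_t"], []).append(p)
        for level_pairs in by_level.values():
            assert len(level_pairs) == 9
            cross = [p for p in level_pairs
                     if p["mixture_source"] != p["reference_source"]]
            assert len(cross) == 6

    def test_single_source_shares_provenance(self):
        sc = Scenario(models=("nb",), p_t_grid=(0.1,), n_source_datasets=1,
                      n_genes=300, n_samples=4, n_replicates=3)
        pairs = build_sim1(sc, seed=2)
        assert len(pairs) == 1
        assert pairs[0]["mixture_source"] == pairs[0]["reference_source"]

    def test_ground_truth_consistency(self):
        sc = Scenario(models=("normal",), p_t_grid=(0.3,), n_genes=300,
                      n_samples=4, n_replicates=3)
        for p in build_sim1(sc, seed=3):
            ms = p["mixture_set"]
            np.testing.assert_allclose(
                ms.truth_absolute.values / ms.truth_absolute.values.sum(axis=0),
                ms.truth_relative.values, atol=1e-9,
            )


class TestBuildSim1Libsize:
    def test_two_group_library_sizes_recovered(self):
        sc = Scenario(p_t_grid=(0.1,), n_genes=10_000, n_samples=20,
                      n_replicates=3, units=("count",))
        (ms,) = build_sim1_libsize(sc, seed=4)
        totals = ms.mixture.values.sum(axis=0)
        assert totals.iloc[:10].mean() == pytest.approx(12e6, rel=0.01)
        assert totals.iloc[10:].mean() == pytest.approx(24e6, rel=0.01)
        assert totals.iloc[10:].mean() / totals.iloc[:10].mean() == pytest.approx(2.0, rel=0.02)

    def test_cpm_conversion_removes_library_split(self):
        sc = Scenario(p_t_grid=(0.1,), n_genes=2000, n_samples=8,
                      n_replicates=3, units=("count", "cpm"))
        count_set, cpm_set = build_sim1_libsize(sc, seed=5)
        np.testing.assert_allclose(cpm_set.mixture.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_odd_sample_count_rejected(self):
        sc = Scenario(p_t_grid=(0.1,), n_genes=300, n_samples=5, n_replicates=3)
        with pytest.raises(ValueError):
            build_sim1_libsize(sc, seed=6)


@pytest.fixture(scope="module")
def sim2_source():
    all_types = sorted({ct for K in (5, 10) for ct in COMPONENT_ROSTERS[K]})
    return generate_source_profiles(
        800, all_types, n_replicates=3,
        seed=_stream_seed(7, "sim2", "source"), dataset_tag="sim2src",
    )


@pytest.fixture(scope="module")
def sim3_inputs():
    all_types = sorted(COMPONENT_ROSTERS[5])
    src = generate_source_profiles(600, all_types, n_replicates=3,
                                   seed=8, dataset_tag="imm")
    tumor = generate_source_profiles(600, ["hct"], n_replicates=3,
                                     seed=9, dataset_tag="tum")
    sc = Scenario(component_gradient=(5,), regimes=("orthog", "uniform"),
                  n_genes=600, n_samples=6, n_replicates=3)
    sets = build_sim2(sc, seed=8, source=src)
    return src, tumor, sets


class TestBuildSim2:
    def test_set_count_and_rosters(self, sim2_source):
        sc = Scenario(component_gradient=(5, 10), regimes=("orthog", "real"),
                      n_genes=800, n_samples=12, n_replicates=3)
        sets = build_sim2(sc, seed=7, source=sim2_source)
        assert len(sets) == 4  # 2 gradients x 2 regimes
        rosters = {frozenset(ms.known_cell_types) for ms in sets}
        assert frozenset(COMPONENT_ROSTERS[5]) in rosters
        assert frozenset(COMPONENT_ROSTERS[10]) in rosters

    def test_comp5_roster_contents(self):
        assert set(COMPONENT_ROSTERS[5]) == {"T", "B", "monocytes", "neutrophils", "NK"}

    def test_comp10_splits_t_and_b(self):
        r10 = set(COMPONENT_ROSTERS[10])
        assert {"CD4 T", "CD8 T", "naive B", "memory B"} <= r10
        assert "T" not in r10 and "B" not in r10


class TestBuildSim3:
    def test_cartesian_product_of_spike_groups(self, sim3_inputs):
        src, tumor, sets = sim3_inputs
        out = build_sim3(sets, tumor, spike_groups=("small", "large", "mosaic"),
                         seed=10, source=src)
        assert len(out) == len(sets) * 3

    def test_dual_truth_scale_relation(self, sim3_inputs):
        src, tumor, sets = sim3_inputs
        out = build_sim3(sets, tumor, spike_groups=("small",), seed=11, source=src)
        ms = out[0]
        t = ms.truth_absolute.values.loc["tumor"]
        immune_abs = ms.truth_absolute.values.drop(index="tumor")
        np.testing.assert_allclose(
            immune_abs, ms.truth_relative.values * (1.0 - t), atol=1e-12
        )

    def test_tumor_label_collision_rejected(self, sim3_inputs):
        src, tumor, sets = sim3_inputs
        with pytest.raises(ValueError):
            build_sim3(sets, tumor, spike_groups=("small",), seed=12,
                       source=src, tumor_label="T")


def test_unit_invariance_of_baseline_under_fixed_library(small_source):
    """count vs cpm input gives identical baseline estimates at fixed L."""
    roster = small_source.cell_types
    w = make_uniform(3, 6, seed=13, cell_types=roster)
    expected = mix_expected(small_source, w)
    spec = NoiseSpec(model="nb", p_t=0.1, library_size=1e6, seed=14)
    mix = apply_noise(expected, spec, mode="component_level", w=w, src=small_source)
    ref = build_reference(small_source, roster)
    est_count = nnls_deconvolve(mix, ref)
    est_cpm = nnls_deconvolve(convert_units(mix, "cpm"), ref)
    np.testing.assert_allclose(est_count.values, est_cpm.values, atol=1e-6)


def test_stream_seed_independence():
    """Changing one stage's label leaves other streams untouched."""
    assert _stream_seed(1, "sim1", "noise") == _stream_seed(1, "sim1", "noise")
    assert _stream_seed(1, "sim1", "noise") != _stream_seed(1, "sim2", "noise")
    assert 0 <= _stream_seed(123, "x") < 2**31
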