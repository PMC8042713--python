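"""Marker selection (percentile + relaxation) and signature selection."""

import numpy as np
import pandas as pd
import pytest

from deconvbench import (
    MarkerCriteria,
    de_test_all_pairs,
    de_test_default,
    markers_at_fraction,
    select_markers,
    select_signature,
)

from conftest import expr


def naive_markers(replicates, p, high_pct=80, low_pct=50):
    """Brute-force enumeration of the percentile criteria (independent oracle)."""
    cell_types = list(replicates)
    genes = list(next(iter(replicates.values())).gene_ids)
    out = {ct: [] for ct in cell_types}
    for g in genes:
        for ct in cell_types:
            m = replicates[ct]
            n_high = 0
            for s in m.sample_ids:
                col = m.values[s]
                if col[g] > np.percentile(col, high_pct):
                    n_high += 1
            if n_high / m.n_samples < p - 1e-12:
                continue
            low_everywhere = True
            for other in cell_types:
                if other == ct:
                    continue
                mo = replicates[other]
                n_low = sum(
                    mo.values.loc[g, s] < np.percentile(mo.values[s], low_pct)
                    for s in mo.sample_ids
                )
                if n_low / mo.n_samples < p - 1e-12:
                    low_everywhere = False
                    break
            if low_everywhere:
                out[ct].append(g)
    return out


def toy_replicates(n_odd_a_samples=0):
    """20-gene toy: genes 0-1 mark A, 2-3 mark B, 4-5 mark C, rest background.

    ``n_odd_a_samples`` of A's 25 samples have the A markers silenced, which
    drops their qualifying sample fraction below 1.
    """
    rng = np.random.default_rng(0)
    reps = {}
    for t, ct in enumerate("ABC"):
        n = 25 if ct == "A" else 5
        vals = np.full((20, n), 100.0) + rng.uniform(0, 1, size=(20, n))
        own = {"A": (0, 1), "B": (2, 3), "C": (4, 5)}
        for c2, idxs in own.items():
            for g in idxs:
                vals[g, :] = 1000.0 if c2 == ct else 1.0
        if ct == "A" and n_odd_a_samples:
            for g in (0, 1):
                vals[g, n - n_odd_a_samples:] = 1.0
        reps[ct] = expr(vals, sample_ids=[f"{ct}{j}" for j in range(n)])
    return reps


class TestSelectMarkers:
    def test_agrees_with_brute_force_oracle(self):
        reps = toy_replicates()
        got = markers_at_fraction(reps, 0.95)
        want = naive_markers(reps, 0.95)
        assert {ct: sorted(v) for ct, v in got.items()} == \
               {ct: sorted(v) for ct, v in want.items()}
        assert got["A"] == ["g0", "g1"]

    def test_one_relaxation_step_recovers_imperfect_markers(self):
        # A's markers qualify in 23/25 samples: fail at p = 0.95, pass at 0.92
        reps = toy_replicates(n_odd_a_samples=2)
        assert markers_at_fraction(reps, 0.95)["A"] == []
        assert markers_at_fraction(reps, 0.92)["A"] == ["g0", "g1"]
        final = select_markers(reps, MarkerCriteria(p=0.95, s=0.03))
        assert final["A"] == ["g0", "g1"]

    def test_identical_profiles_error(self):
        vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 3))
        reps = {"A": expr(vals), "B": expr(vals)}
        with pytest.raises(ValueError, match="no marker genes"):
            select_markers(reps)

    def test_relaxation_monotonicity(self):
        reps = toy_replicates(n_odd_a_samples=2)
        for ct in "ABC":
            at_95 = set(markers_at_fraction(reps, 0.95)[ct])
            at_92 = set(markers_at_fraction(reps, 0.92)[ct])
            at_80 = set(markers_at_fraction(reps, 0.80)[ct])
            assert at_95 <= at_92 <= at_80

    def test_marker_sets_disjoint(self, small_source):
        markers = select_markers(small_source.replicates)
        all_markers = [g for v in markers.values() for g in v]
        assert len(all_markers) == len(set(all_markers))

    def test_embedded_marker_recovery(self, small_source):
        """>= 90% of embedded markers recovered, <= 5% spurious at fold 50."""
        markers = select_markers(small_source.replicates)
        for ct, embedded in small_source.marker_genes.items():
            got = set(markers[ct])
            emb = set(embedded)
            recovered = len(got & emb) / len(emb)
            spurious = len(got - emb) / max(len(got), 1)
            assert recovered >= 0.90, f"{ct}: recovered {recovered:.2f}"
            assert spurious <= 0.05, f"{ct}: spurious {spurious:.2f}"


class TestDeTestDefault:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(100, size=(50, 4)).astype(float)
        a, b = expr(vals), expr(vals)
        res = de_test_default(a, b)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["padj"] > 0.05).all()

    def test_constructed_large_effect_detected(self):
        # gene 0 at ~2^12 vs ~2^2 against a flat 500-gene background: the
        # background keeps library sizes comparable, so the transformed fold
        # change lands near its nominal value
        rng = np.random.default_rng(2)
        a = rng.poisson(1000, size=(500, 6)).astype(float)
        b = rng.poisson(1000, size=(500, 6)).astype(float)
        a[0] = rng.poisson(4096, size=6)
        b[0] = rng.poisson(4, size=6)
        res = de_test_default(expr(a), expr(b))
        top = res.iloc[0]
        assert top["log2fc"] == pytest.approx(10.0, abs=1.0)
        assert top["padj"] == res["padj"].min()
        assert top["padj"] < 0.01
        others = res.iloc[1:]
        assert others["log2fc"].abs().mean() < 0.1
        assert (others["padj"] < 0.01).mean() < 0.05

    def test_within_group_label_permutation_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(50, size=(30, 5)).astype(float)
        b = rng.poisson(60, size=(30, 5)).astype(float)
        res1 = de_test_default(expr(a), expr(b))
        res2 = de_test_default(expr(a[:, ::-1]), expr(b[:, [2, 0, 1, 4, 3]]))
        np.testing.assert_allclose(res1["pvalue"], res2["pvalue"], rtol=1e-10)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            de_test_default(expr([[1.0]]), expr([[1.0, 2.0]]))


class TestSelectSignature:
    def make_de(self):
        return pd.DataFrame({
            "pair": ["A_vs_B"] * 3 + ["A_vs_C"] * 3,
            "gene_id": ["g1", "g2", "g3"] * 2,
            "log2fc": [12.0, 12.0, 9.9, 12.0, -11.0, 9.9],
            "padj": [0.005, 0.02, 0.001, 0.5, 0.002, 0.001],
        })

    def test_both_thresholds_required(self):
        sig = select_signature(self.make_de(), padj_max=0.01, lfc_min=10)
        # g1 passes in A_vs_B only; g2 fails padj there but g2 passes in
        # A_vs_C (|−11| >= 10, padj 0.002); g3 fails the fold threshold
        assert sig == ["g1", "g2"]

    def test_intersection_rule(self):
        sig = select_signature(self.make_de(), padj_max=0.01, lfc_min=10,
                               rule="intersection")
        assert sig == []

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_signature(pd.DataFrame())


def test_signature_pipeline_on_synthetic_markers(small_source):
    """Marker genes carry extreme fold changes, so they dominate the signature."""
    de = de_test_all_pairs(small_source.replicates)
    sig = set(select_signature(de, padj_max=0.01, lfc_min=4.0))
    embedded = {g for v in small_source.marker_genes.values() for g in v}
    assert len(sig & embedded) / len(embedded) >= 0.9
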