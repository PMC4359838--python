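"""Information curves: pairwise/cumulative MI, coverage, 95% selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ltmclust as L
from ltmclust.curves import CurveEntry, InformationCurve, cumulative_mi
from ltmclust.errors import DegenerateLatentError
from ltmclust.model import (
    LatentTreeModel,
    VariableSpec,
    enumerate_joint,
    full_joint,
    mutual_information,
)
from ltmclust.synthetic import random_model


def copies_model(k=2, flip=0.0, prior=0.5):
    """Latent H with k manifests that copy it (error ``flip``)."""
    specs = [VariableSpec("H", "latent", 2)] + [
        VariableSpec(f"x{i}", "manifest", 2) for i in range(k)
    ]
    edges = [("H", f"x{i}") for i in range(k)]
    cpts = {"H": [1 - prior, prior]}
    for i in range(k):
        cpts[f"x{i}"] = [[1 - flip, flip], [flip, 1 - flip]]
    return LatentTreeModel(specs, edges, cpts)


class TestPairwiseMI:
    def test_independent_pair_has_zero_mi(self):
        m = copies_model(k=1, flip=0.5)
        assert L.pairwise_mi(m, "H", "x0") == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_copy_is_one_bit(self):
        m = copies_model(k=1, flip=0.0)
        assert L.pairwise_mi(m, "H", "x0") == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_latents=int(rng.integers(1, 3)),
                         n_manifests=int(rng.integers(1, 6)))
        latent = m.latent_names[0]
        manifest = m.manifest_names[int(rng.integers(0, len(m.manifest_names)))]
        want = mutual_information(enumerate_joint(m, [latent, manifest]))
        assert L.pairwise_mi(m, latent, manifest) == pytest.approx(want, abs=1e-9)


class TestCumulativeMI:
    def test_single_manifest_equals_pairwise(self, small_model):
        m = small_model
        x = m.manifest_names[0]
        lat = m.latent_names[0]
        assert cumulative_mi(m, lat, [x]) == pytest.approx(
            L.pairwise_mi(m, lat, x), abs=1e-9
        )

    def test_matches_oracle_joint_mi(self, rng):
        for _ in range(5):
            m = random_model(rng, n_latents=2, n_manifests=4)
            lat = m.latent_names[-1]
            cols = m.manifest_names[:3]
            # oracle: MI from the enumerated (latent, cols) joint tensor
            sub = full_joint(m).marginal([lat] + cols)
            t = sub.table.reshape(m.card(lat), -1)
            py = t.sum(axis=1, keepdims=True)
            px = t.sum(axis=0, keepdims=True)
            mask = t > 0
            want = (t[mask] * np.log2(t[mask] / (py @ px)[mask])).sum()
            assert cumulative_mi(m, lat, cols) == pytest.approx(want, abs=1e-9)

    def test_monte_carlo_agrees_with_exact_within_three_se(self, rng):
        m = random_model(rng, n_latents=2, n_manifests=10)
        lat = m.latent_names[0]
        cols = m.manifest_names
        exact = cumulative_mi(m, lat, cols)
        mc, se = cumulative_mi(
            m, lat, cols, exact_limit=2, n_samples=100_000, seed=42, return_se=True
        )
        assert se > 0
        assert abs(mc - exact) < 3 * se + 1e-6

    def test_adding_a_variable_never_decreases_joint_mi(self, small_model):
        m = small_model
        lat = m.latent_names[0]
        cols = m.manifest_names
        vals = [cumulative_mi(m, lat, cols[: k + 1]) for k in range(len(cols))]
        assert np.all(np.diff(vals) >= -1e-9)


class TestInformationCurve:
    def test_two_deterministic_copies_cover_at_first_entry(self):
        m = copies_model(k=2, flip=0.0)
        curve = L.information_curve(m, "H")
        assert curve.entries[0].coverage == pytest.approx(100.0, abs=1e-6)

    def test_final_coverage_is_always_100(self, small_model):
        for lat in small_model.latent_names:
            try:
                curve = L.information_curve(small_model, lat)
            except DegenerateLatentError:
                continue
            assert curve.entries[-1].coverage == pytest.approx(100.0, abs=0.01)

    def test_entries_sorted_and_cumulative_monotone(self, rng):
        for _ in range(5):
            m = random_model(rng, n_latents=2, n_manifests=6)
            curve = L.information_curve(m, m.latent_names[0])
            pmi = [e.pairwise_mi for e in curve.entries]
            assert pmi == sorted(pmi, reverse=True)
            cmi = [e.cumulative_mi for e in curve.entries]
            assert np.all(np.diff(cmi) >= -1e-12)
            assert all(e.pairwise_mi >= 0 for e in curve.entries)

    def test_recomputation_is_stable(self, small_model):
        a = L.information_curve(small_model, small_model.latent_names[0], seed=5)
        b = L.information_curve(small_model, small_model.latent_names[0], seed=5)
        assert a.manifests() == b.manifests()
        assert [e.coverage for e in a.entries] == [e.coverage for e in b.entries]

    def test_degenerate_latent_raises(self):
        m = copies_model(k=2, flip=0.5)
        with pytest.raises(DegenerateLatentError):
            L.information_curve(m, "H")

    def test_coverage_is_base_free(self):
        # coverage is a ratio of MIs, so a change of log base cancels; verify
        # coverage values match ratios of the curve's own cumulative entries
        m = copies_model(k=3, flip=0.2)
        curve = L.information_curve(m, "H")
        total = curve.entries[-1].cumulative_mi
        for e in curve.entries:
            assert e.coverage == pytest.approx(100 * e.cumulative_mi / total)

    def test_strong_pair_reaches_95_in_two_entries(self):
        # a latent with two high-fidelity manifests and three weak satellites:
        # the two strong entries alone carry >= 95% of the information
        specs = [VariableSpec("Y8", "latent", 2)]
        names = ["fever", "hectic fever", "rapid pulse", "ascites", "pale lips"]
        flips = [0.05, 0.05, 0.4, 0.4, 0.4]
        edges, cpts = [], {"Y8": [0.7, 0.3]}
        for n, f in zip(names, flips):
            specs.append(VariableSpec(n, "manifest", 2))
            edges.append(("Y8", n))
            cpts[n] = [[1 - f, f], [f, 1 - f]]
        m = LatentTreeModel(specs, edges, cpts)
        curve = L.information_curve(m, "Y8")
        sel = L.select_significant(curve, 95.0)
        assert sel == ["fever", "hectic fever"]


class TestSelectSignificant:
    def make_curve(self, coverages):
        entries = [
            CurveEntry(f"m{i}", 1.0 - i * 0.1, c, c) for i, c in enumerate(coverages)
        ]
        return InformationCurve("Y", entries, [e.manifest for e in entries])

    def test_threshold_100_selects_everything(self):
        curve = self.make_curve([60, 96, 99, 100])
        assert L.select_significant(curve, 100) == ["m0", "m1", "m2", "m3"]

    def test_95_rule_shortest_prefix(self):
        curve = self.make_curve([60, 96, 99, 100])
        assert L.select_significant(curve, 95) == ["m0", "m1"]

    def test_threshold_0_keeps_first_entry_only(self):
        curve = self.make_curve([60, 96, 99, 100])
        assert L.select_significant(curve, 0) == ["m0"]
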