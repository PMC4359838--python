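"""Joint clustering of latent variables sharing a syndrome factor."""

import numpy as np
import pytest

import ltmclust as L
from ltmclust.errors import ConfigurationError
from ltmclust.jcm import FactorSpec, SyndromeFactorMap, study_factor_map, subdivide
from ltmclust.synthetic import (
    BackboneEdge,
    Block,
    Member,
    PlantedSpec,
    make_planted_model,
)


class TestApplyExclusions:
    def test_empty_exclusion_is_identity(self):
        sel = ["a", "b", "c"]
        assert L.apply_exclusions(sel, []) == sel

    def test_study_qi_stagnation_list(self):
        selected = [
            "stomach bloating", "chills", "hypochondriac pain", "stomachache",
            "dizziness", "chest distress", "abdominal distension",
        ]
        out = L.apply_exclusions(selected, ["chills", "dizziness"])
        assert out == [
            "stomach bloating", "hypochondriac pain", "stomachache",
            "chest distress", "abdominal distension",
        ]

    def test_absent_exclusions_ignored(self):
        assert L.apply_exclusions(["a", "b"], ["z"]) == ["a", "b"]

    def test_excluding_everything_gives_empty_list(self):
        assert L.apply_exclusions(["a", "b"], ["b", "a"]) == []


class TestFactorMap:
    def test_shipped_map_has_five_factors_with_study_members(self):
        fmap = study_factor_map()
        assert list(fmap.factors) == [
            "Qi-stagnation", "dampness", "blood-stasis", "heat", "deficiency",
        ]
        assert fmap.factors["Qi-stagnation"].latents == ("Y0", "Y1", "Y9")
        assert fmap.factors["blood-stasis"].latents == ("Y0", "Y2", "Y4", "Y7", "Y9")
        assert set(fmap.factors["blood-stasis"].exclusions) == {
            "slippery pulse", "plump tongue",
        }

    def test_json_round_trip(self, tmp_path):
        fmap = study_factor_map()
        p = tmp_path / "map.json"
        fmap.save(p)
        again = SyndromeFactorMap.load(p)
        assert again == fmap

    def test_unknown_latent_rejected_against_model(self, one_block_model):
        fmap = SyndromeFactorMap({"f": FactorSpec(("nope",))})
        with pytest.raises(ConfigurationError, match="unknown latent"):
            fmap.validate(one_block_model)


def overlapping_factor_spec(n_records=2000, seed=0):
    """Two factors sharing latent C; blocks strongly loaded."""
    blocks = [
        Block("A", 2, tuple(Member(f"a{i}", 0.7) for i in range(3))),
        Block("B", 2, tuple(Member(f"b{i}", 0.7) for i in range(3))),
        Block("C", 2, tuple(Member(f"c{i}", 0.7) for i in range(2))),
    ]
    backbone = [BackboneEdge("C", "A", 0.6), BackboneEdge("C", "B", 0.1)]
    return PlantedSpec(blocks, backbone, n_records=n_records, seed=seed)


class TestBuildJcm:
    def test_single_member_factor_equals_its_significant_list(self):
        spec = overlapping_factor_spec()
        truth = make_planted_model(spec)
        data = L.sample_cohort(truth, 2000, seed=1)
        base = L.fit_em(truth, data, restarts=2, seed=2, init_model=truth).model
        fmap = SyndromeFactorMap({"solo": FactorSpec(("B",))})
        jcm = L.build_jcm(base, data, "solo", fmap, seed=3)
        curve = L.information_curve(base, "B")
        assert jcm.pooled_manifests == L.select_significant(curve)
        assert jcm.selected == jcm.selected_raw

    def test_exclusions_removed_from_selection(self):
        spec = overlapping_factor_spec()
        truth = make_planted_model(spec)
        data = L.sample_cohort(truth, 2000, seed=4)
        base = L.fit_em(truth, data, restarts=2, seed=5, init_model=truth).model
        fmap = SyndromeFactorMap(
            {"f": FactorSpec(("A", "C"), exclusions=("a1", "c0"))}
        )
        jcm = L.build_jcm(base, data, "f", fmap, seed=6)
        assert "a1" not in jcm.selected
        assert "c0" not in jcm.selected
        assert [m for m in jcm.selected_raw if m not in ("a1", "c0")] == jcm.selected

    def test_planted_factor_recovered_across_seeds(self):
        """Z's selected list matches the planted factor's manifests."""
        hits = 0
        for seed in range(10):
            spec = overlapping_factor_spec(seed=seed)
            truth = make_planted_model(spec)
            data = L.sample_cohort(truth, 2000, seed=100 + seed)
            base = L.fit_em(truth, data, restarts=2, seed=seed,
                            init_model=truth).model
            fmap = SyndromeFactorMap({"f": FactorSpec(("A", "C"))})
            jcm = L.build_jcm(base, data, "f", fmap, seed=seed)
            want = {"a0", "a1", "a2", "c0", "c1"}
            got = set(jcm.selected)
            jac = len(want & got) / len(want | got)
            hits += jac >= 0.8
        assert hits >= 8

    def test_empty_factor_rejected(self, one_block_model):
        fmap = SyndromeFactorMap({"f": FactorSpec(())})
        data = L.sample_cohort(one_block_model, 50, seed=0)
        with pytest.raises(ConfigurationError):
            L.build_jcm(one_block_model, data, "f", fmap)


def three_state_mixture(n_records=5000, seed=0):
    """Baseline state plus two disjoint active blocks (a Z5-like planted mix)."""
    members = tuple(
        Member(f"a{i}", p_given_state=(0.15, 0.85, 0.15)) for i in range(3)
    ) + tuple(Member(f"b{i}", p_given_state=(0.15, 0.15, 0.85)) for i in range(3))
    blocks = [Block("M", 3, members, prior=(0.5, 0.25, 0.25))]
    return PlantedSpec(blocks, [], n_records=n_records, seed=seed)


class TestCardinalityAndSubdivision:
    def test_three_state_mixture_assigned_cardinality_three(self):
        spec = three_state_mixture()
        truth = make_planted_model(spec)
        data = L.sample_cohort(truth, 5000, seed=9)
        choice = L.choose_cardinality(data, data.symptoms, seed=1)
        assert choice.cardinality == 3

    def test_two_state_mixture_assigned_cardinality_two(self):
        spec = L.independent_blocks_spec(1, 6, strength=0.7, n_records=5000, seed=3)
        truth = L.make_planted_model(spec)
        data = L.sample_cohort(truth, 5000, seed=10)
        choice = L.choose_cardinality(data, data.symptoms, seed=2)
        assert choice.cardinality == 2

    def test_pure_noise_gets_lower_bound_with_bic_gap(self):
        rng = np.random.default_rng(1)
        vals = (rng.random((1500, 5)) < 0.4).astype(int)
        data = L.SymptomMatrix(vals, [f"n{i}" for i in range(5)])
        choice = L.choose_cardinality(data, data.symptoms, seed=3)
        assert choice.cardinality == 2
        assert choice.bics[2] > choice.bics[3]

    def test_planted_split_recovers_blocks_and_is_label_invariant(self):
        spec = three_state_mixture()
        truth = make_planted_model(spec)
        data = L.sample_cohort(truth, 5000, seed=12)
        fmap = SyndromeFactorMap({"f": FactorSpec(("M",))})
        jcm = L.build_jcm(truth, data, "f", fmap, seed=4)
        assert jcm.cardinality == 3
        assert len(jcm.subsyndromes) == 2
        parts = sorted(sorted(s.manifests) for s in jcm.subsyndromes)
        assert parts == [["a0", "a1", "a2"], ["b0", "b1", "b2"]]
        # disjoint and inside the pool
        s1, s2 = (set(s.manifests) for s in jcm.subsyndromes)
        assert not (s1 & s2)
        assert (s1 | s2) <= set(jcm.pooled_manifests)
        # refitting with another seed permutes states but not the partition
        jcm2 = L.build_jcm(truth, data, "f", fmap, seed=99)
        parts2 = sorted(sorted(s.manifests) for s in jcm2.subsyndromes)
        assert parts2 == parts

    def test_two_state_jcm_is_not_subdivided(self):
        spec = L.independent_blocks_spec(1, 4, strength=0.7, n_records=800, seed=5)
        truth = L.make_planted_model(spec)
        data = L.sample_cohort(truth, 800, seed=13)
        fmap = SyndromeFactorMap({"f": FactorSpec(("B0",))})
        jcm = L.build_jcm(truth, data, "f", fmap, seed=5)
        assert jcm.cardinality == 2
        assert jcm.subsyndromes == []
        assert subdivide(jcm, data) == []
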