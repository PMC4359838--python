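"""Latent tree model invariants and exact-inference oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ltmclust as L
from ltmclust.errors import ModelInvariantError, UndefinedPosteriorError
from ltmclust.model import (
    LatentTreeModel,
    VariableSpec,
    full_joint,
    mutual_information,
    node_marginals,
    pair_marginal,
    record_loglikelihoods,
    sample_model,
)
from ltmclust.synthetic import random_model


def chain_model(p_root=0.3, flip=0.1):
    """Root latent -> one manifest copying the root with error ``flip``."""
    return LatentTreeModel(
        [VariableSpec("H", "latent", 2), VariableSpec("x", "manifest", 2)],
        [("H", "x")],
        {"H": [1 - p_root, p_root], "x": [[1 - flip, flip], [flip, 1 - flip]]},
    )


class TestModelInvariants:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ModelInvariantError, match="sum"):
            chain = chain_model()
            LatentTreeModel(
                list(chain.variables.values()), chain.edges(),
                {"H": [0.5, 0.4], "x": chain.cpts["x"]},
            )

    def test_manifest_must_be_leaf(self):
        with pytest.raises(ModelInvariantError, match="leaf"):
            LatentTreeModel(
                [
                    VariableSpec("H", "latent", 2),
                    VariableSpec("x", "manifest", 2),
                    VariableSpec("y", "manifest", 2),
                ],
                [("H", "x"), ("x", "y")],
                {
                    "H": [0.5, 0.5],
                    "x": [[0.5, 0.5], [0.5, 0.5]],
                    "y": [[0.5, 0.5], [0.5, 0.5]],
                },
            )

    def test_disconnected_edges_rejected(self):
        with pytest.raises(ModelInvariantError):
            LatentTreeModel(
                [VariableSpec("H", "latent", 2), VariableSpec("G", "latent", 2)],
                [],
                {"H": [0.5, 0.5], "G": [0.5, 0.5]},
            )

    def test_json_round_trip(self, small_model, tmp_path):
        path = tmp_path / "m.json"
        small_model.save(path)
        again = LatentTreeModel.load(path)
        assert again.topo_order == small_model.topo_order
        for n in small_model.variables:
            np.testing.assert_allclose(again.cpts[n], small_model.cpts[n])

    def test_dot_export_mentions_every_node(self, small_model):
        dot = small_model.to_dot()
        for n in small_model.variables:
            assert f'"{n}"' in dot


class TestLoglikelihood:
    def test_independent_fair_coins_closed_form(self):
        cols = [f"x{i}" for i in range(5)]
        m = L.latent_class_skeleton(cols, 2)
        data = {c: np.array([1]) for c in cols}
        assert L.loglikelihood(m, data) == pytest.approx(-5 * math.log(2))

    def test_duplicating_records_doubles_loglik(self, small_model, rng):
        draw = sample_model(small_model, 4, rng)
        once = {c: draw[c] for c in small_model.manifest_names}
        twice = {c: np.concatenate([v, v]) for c, v in once.items()}
        assert L.loglikelihood(small_model, twice) == pytest.approx(
            2 * L.loglikelihood(small_model, once)
        )

    def test_latent_state_relabeling_leaves_likelihood_unchanged(self, rng):
        m = random_model(rng, n_latents=1, n_manifests=4, max_card=3)
        perm = list(rng.permutation(m.card("H0")))
        cpts = {n: t.copy() for n, t in m.cpts.items()}
        cpts["H0"] = cpts["H0"][perm]
        for c in m.children["H0"]:
            cpts[c] = cpts[c][perm]
        m2 = LatentTreeModel(list(m.variables.values()), m.edges(), cpts)
        data = sample_model(m, 20, rng)
        ev = {c: data[c] for c in m.manifest_names}
        assert L.loglikelihood(m2, ev) == pytest.approx(L.loglikelihood(m, ev))

    def test_single_latent_mixture_closed_form(self, one_block_model):
        m = one_block_model
        x = {c: np.array([1]) for c in m.manifest_names}
        prior = m.cpts[m.root]
        expected = sum(
            prior[s] * np.prod([m.cpts[c][s, 1] for c in m.manifest_names])
            for s in range(2)
        )
        assert L.loglikelihood(m, x) == pytest.approx(math.log(expected))


class TestOracleEquivalence:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_message_passing_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(
            rng,
            n_latents=int(rng.integers(1, 4)),
            n_manifests=int(rng.integers(2, 8)),
        )
        joint = full_joint(m).marginal(m.manifest_names)
        draw = sample_model(m, 3, rng)
        ev = {c: draw[c] for c in m.manifest_names}
        lls = record_loglikelihoods(m, ev)
        for i in range(3):
            idx = tuple(int(ev[c][i]) for c in m.manifest_names)
            assert lls[i] == pytest.approx(math.log(joint.table[idx]), abs=1e-9)

    def test_posterior_matches_oracle(self, small_model, rng):
        m = small_model
        cols = m.manifest_names
        x = {c: int(rng.integers(0, 2)) for c in cols}
        for latent in m.latent_names:
            sub = full_joint(m).marginal([latent] + cols)
            t = sub.table
            for c in cols:
                t = np.take(t, x[c], axis=1)
            expected = t / t.sum()
            got = L.posterior(m, x, latent)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_marginal_consistency_of_enumerate_joint(self, small_model):
        m = small_model
        a, b = m.manifest_names[:2]
        two = L.enumerate_joint(m, [a, b])
        one = L.enumerate_joint(m, [a])
        np.testing.assert_allclose(two.table.sum(axis=1), one.table, atol=1e-12)

    def test_pair_marginal_matches_enumeration(self, rng):
        for _ in range(10):
            m = random_model(rng, n_latents=int(rng.integers(1, 4)),
                             n_manifests=int(rng.integers(2, 6)))
            names = list(m.variables)
            a, b = rng.choice(names, size=2, replace=False)
            got = pair_marginal(m, a, b).table
            want = L.enumerate_joint(m, [a, b]).table
            np.testing.assert_allclose(got, want, atol=1e-10)


class TestPosteriorEdgeCases:
    def test_latent_independent_of_evidence_keeps_prior(self):
        m = chain_model(p_root=0.3, flip=0.5)  # manifest carries no information
        post = L.posterior(m, {"x": 1}, "H")
        np.testing.assert_allclose(post, [0.7, 0.3], atol=1e-12)

    def test_deterministic_child_pins_posterior(self):
        m = chain_model(p_root=0.5, flip=0.0)
        post = L.posterior(m, {"x": 1}, "H")
        # the inference floor leaves a sliver of mass on the impossible state
        assert post[1] == pytest.approx(1.0, abs=1e-9)

    def test_zero_probability_evidence_raises(self):
        m = LatentTreeModel(
            [VariableSpec("H", "latent", 2), VariableSpec("x", "manifest", 2)],
            [("H", "x")],
            {"H": [1.0, 0.0], "x": [[1.0, 0.0], [0.0, 1.0]]},
        )
        with pytest.raises(UndefinedPosteriorError):
            L.posteriors(m, {"x": np.array([1])}, floor=0.0)


class TestSampling:
    def test_same_seed_reproduces_cohort(self, one_block_model):
        a = L.sample_cohort(one_block_model, 50, seed=7)
        b = L.sample_cohort(one_block_model, 50, seed=7)
        c = L.sample_cohort(one_block_model, 50, seed=8)
        assert a == b
        assert a != c

    def test_rejects_empty_sample(self, one_block_model):
        with pytest.raises(ValueError):
            L.sample_cohort(one_block_model, 0, seed=1)

    def test_column_means_near_model_marginals(self, one_block_model):
        cohort = L.sample_cohort(one_block_model, 10000, seed=3)
        marg = node_marginals(one_block_model)
        for c in cohort.symptoms:
            p = marg[c][1]
            se = math.sqrt(p * (1 - p) / 10000)
            assert abs(cohort.column(c).mean() - p) < 3 * se


def test_mutual_information_of_deterministic_copy_is_one_bit():
    m = chain_model(p_root=0.5, flip=0.0)
    assert mutual_information(pair_marginal(m, "H", "x")) == pytest.approx(1.0, abs=1e-6)
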