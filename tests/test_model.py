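"""The physics node operator and pairwise-interaction extraction."""

import numpy as np
import pytest
from springedge import AnalyticSpringEdge

from newtongn import FeatureLayout, PhysicsGN, SystemSpec, node_force_operator
from newtongn.graphs import build_full_graph, sample_from_state
from newtongn.model import load_checkpoint, save_checkpoint
from newtongn.systems import pairwise_force, sample_initial_state


def _spring_sample(seed=0, n=5, layout=None):
    spec = SystemSpec(law="spring", d=2)
    state = sample_initial_state(n, spec, seed=seed)
    return sample_from_state(
        state.positions,
        state.velocities,
        state.charges,
        state.masses,
        layout or FeatureLayout(d=2),
    )


def _small_model(mode, seed=0, activation="silu"):
    return PhysicsGN(
        FeatureLayout(d=2),
        mode=mode,
        hidden_layers=2,
        hidden_units=16,
        activation=activation,
        seed=seed,
    )


class TestNodeForceOperator:
    def test_hand_case(self):
        msgs = np.array([[1.0, 0.0], [0.0, 1.0]])
        recv = np.array([0, 0])
        acc = node_force_operator(msgs, recv, np.array([2.0]))
        np.testing.assert_allclose(acc, [[0.5, 0.5]])

    def test_isolated_node_zero(self):
        acc = node_force_operator(np.zeros((0, 2)), np.zeros(0, int), np.ones(3))
        np.testing.assert_array_equal(acc, np.zeros((3, 2)))

    def test_matches_brute_force_loop(self, rng):
        msgs = rng.normal(size=(40, 3))
        recv = rng.integers(0, 6, size=40)
        masses = rng.uniform(0.5, 2.0, size=6)
        acc = node_force_operator(msgs, recv, masses)
        expected = np.zeros((6, 3))
        for e in range(40):
            expected[recv[e]] += msgs[e]
        expected /= masses[:, None]
        np.testing.assert_allclose(acc, expected, atol=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            node_force_operator(np.ones((1, 2)), np.array([0]), np.array([0.0]))


class TestEdgeMessages:
    def test_zero_network_gives_zero_messages(self):
        model = _small_model("force")
        for p in model.params:
            p[...] = 0.0
        sample = _spring_sample()
        assert np.all(model.edge_messages(sample) == 0.0)
        assert np.all(model.predict(sample) == 0.0)

    def test_messages_are_per_edge_independent(self, rng):
        model = _small_model("force", seed=3)
        sample = _spring_sample(seed=1)
        msgs = model.edge_messages(sample)
        perm = rng.permutation(sample.n_edges)
        permuted = sample.edges[perm]
        from newtongn.graphs import GraphSample

        sample2 = GraphSample(
            node_features=sample.node_features,
            edges=permuted,
            masses=sample.masses,
            layout=sample.layout,
        )
        np.testing.assert_allclose(model.edge_messages(sample2), msgs[perm])

    def test_layout_mismatch_rejected(self):
        model = PhysicsGN(FeatureLayout(d=3), mode="force", hidden_layers=1, hidden_units=4)
        with pytest.raises(ValueError):
            model.predict(_spring_sample())


class TestPotentialOperator:
    def test_constant_network_gives_zero_accelerations(self):
        model = _small_model("potential")
        for p in model.params:
            p[...] = 0.0
        model.mlp.bs[-1][...] = 3.7  # constant output
        sample = _spring_sample()
        np.testing.assert_allclose(model.predict(sample), 0.0, atol=1e-14)

    def test_analytic_spring_potential_recovers_spring_force(self):
        """With the closed-form spring potential as the edge function, the
        operator must output exactly the analytic net force over mass."""
        spec = SystemSpec(law="spring", d=2)
        model = _small_model("potential")
        model.mlp = AnalyticSpringEdge(k=2.0, L=1.0, d=2)
        sample = _spring_sample(seed=5, n=6)
        acc = model.predict(sample)
        pos = sample.positions
        expected = np.zeros_like(acc)
        for i in range(6):
            for j in range(6):
                if i != j:
                    expected[i] += pairwise_force(spec, pos[i], pos[j])
        expected /= sample.masses[:, None]
        np.testing.assert_allclose(acc, expected, rtol=1e-6)
        F_hat, P_hat = model.extract_interactions(sample)
        recv, send = sample.edges[:, 0], sample.edges[:, 1]
        F_true = pairwise_force(spec, pos[recv], pos[send])
        np.testing.assert_allclose(F_hat, F_true, rtol=1e-6, atol=1e-10)

    def test_operator_matches_finite_differences(self, rng):
        """Random small network: acceleration = -grad(sum M)/m via FD."""
        model = _small_model("potential", seed=11)
        sample = _spring_sample(seed=2, n=4)
        acc = model.predict(sample)
        h = 1e-5
        fd = np.zeros_like(acc)
        base_feats = sample.node_features.copy()
        for i in range(sample.n):
            for k in range(2):
                for sign, store in ((+1, "up"), (-1, "down")):
                    feats = base_feats.copy()
                    feats[i, k] += sign * h
                    from newtongn.graphs import GraphSample

                    s = GraphSample(
                        node_features=feats,
                        edges=sample.edges,
                        masses=sample.masses,
                        layout=sample.layout,
                    )
                    msgs = model.edge_messages(s)[:, 0]
                    total_in = msgs[s.edges[:, 0] == i].sum()
                    if sign > 0:
                        up = total_in
                    else:
                        down = total_in
                fd[i, k] = -(up - down) / (2 * h) / sample.masses[i]
        np.testing.assert_allclose(acc, fd, rtol=1e-4, atol=1e-8)

    def test_relu_rejected_in_potential_mode(self):
        with pytest.raises(ValueError, match="activation"):
            _small_model("potential", activation="relu")

    def test_gauge_invariance(self):
        """Adding a constant to every message leaves forces unchanged."""
        model = _small_model("potential", seed=4)
        sample = _spring_sample(seed=3)
        acc0 = model.predict(sample)
        F0, P0 = model.extract_interactions(sample)
        model.mlp.bs[-1][...] += 123.456
        acc1 = model.predict(sample)
        F1, P1 = model.extract_interactions(sample)
        np.testing.assert_allclose(acc0, acc1, atol=1e-12)
        np.testing.assert_allclose(F0, F1, atol=1e-12)
        np.testing.assert_allclose(P1 - P0, 123.456, atol=1e-9)


class TestExtraction:
    @pytest.mark.parametrize("mode", ["force", "potential"])
    def test_reaggregation_consistency(self, mode):
        model = _small_model(mode, seed=6)
        sample = _spring_sample(seed=7)
        F_hat, _ = model.extract_interactions(sample)
        acc = node_force_operator(F_hat, sample.edges[:, 0], sample.masses)
        np.testing.assert_allclose(acc, model.predict(sample), atol=1e-10)

    def test_force_mode_linear_in_messages(self):
        model = _small_model("force", seed=8)
        sample = _spring_sample(seed=9)
        acc1 = model.predict(sample)
        model.mlp.Ws[-1][...] *= 2.0
        model.mlp.bs[-1][...] *= 2.0
        np.testing.assert_allclose(model.predict(sample), 2 * acc1, rtol=1e-10)

    def test_parameter_count_is_edge_network_only(self):
        layout = FeatureLayout(d=2)
        model = PhysicsGN(layout, mode="force", hidden_layers=4, hidden_units=300)
        expected = 0
        sizes = [layout.edge_dim] + [300] * 4 + [2]
        for a, b in zip(sizes[:-1], sizes[1:]):
            expected += a * b + b
        assert model.n_params == expected


class TestCheckpoints:
    def test_round_trip(self, tmp_path):
        model = _small_model("potential", seed=10)
        sample = _spring_sample(seed=11)
        path = tmp_path / "ckpt.zip"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.predict(sample), model.predict(sample))
        assert loaded.mode == "potential"
        assert loaded.layout == model.layout

    def test_mismatched_graph_refused(self, tmp_path):
        model = _small_model("force")
        path = tmp_path / "ckpt.zip"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        lj_layout = FeatureLayout(d=3, include_charge=False, include_displacement=True)
        spec = SystemSpec(law="lj", d=3)
        state = sample_initial_state(4, spec, seed=0)
        sample = sample_from_state(
            state.positions, state.velocities, state.charges, state.masses,
            lj_layout, box_length=spec.constants["box_length"],
            r_cut=spec.constants["r_cut"],
        )
        with pytest.raises(ValueError, match="layout"):
            loaded.predict(sample)
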