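import numpy as np
import pytest

from fusewalk.errors import EmptySeedError, InvalidInputError
from fusewalk.propagation import (
    GeneNetwork,
    PropagationConfig,
    build_transition_matrix,
    random_walk_restart,
    solve_stationary_oracle,
)


def random_connected_network(rng, n):
    """Random tree plus extra edges: connected by construction."""
    nodes = [f"n{i}" for i in range(n)]
    edges = [(nodes[i], nodes[int(rng.integers(0, i))]) for i in range(1, n)]
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.append((nodes[i], nodes[j]))
    return GeneNetwork(nodes, edges)


class TestTransitionMatrix:
    def test_triangle_columns(self):
        net = GeneNetwork(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
        T = build_transition_matrix(net).T.toarray()
        for j in range(3):
            col = sorted(T[:, j])
            assert col == pytest.approx([0.0, 0.5, 0.5])
            assert T[:, j].sum() == pytest.approx(1.0, abs=1e-12)

    def test_star_normalization(self):
        net = GeneNetwork(["c", "l1", "l2", "l3"], [("c", "l1"), ("c", "l2"), ("c", "l3")])
        tm = build_transition_matrix(net)
        T = tm.T.toarray()
        idx = {g: i for i, g in enumerate(tm.nodes)}
        for leaf in ("l1", "l2", "l3"):
            assert T[idx["c"], idx[leaf]] == pytest.approx(1.0)
            assert T[idx[leaf], idx["c"]] == pytest.approx(1.0 / 3)

    def test_isolated_node_flagged_dangling(self):
        net = GeneNetwork(["a", "b", "z"], [("a", "b")])
        tm = build_transition_matrix(net)
        assert tm.dangling.tolist() == [False, False, True]
        assert tm.T.toarray()[:, 2].sum() == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            GeneNetwork(["a", "b"], [("a", "b", -1.0)])

    def test_weighted_normalization(self):
        net = GeneNetwork(["a", "b", "c"], [("a", "b", 3.0), ("a", "c", 1.0)])
        T = build_transition_matrix(net).T.toarray()
        assert T[1, 0] == pytest.approx(0.75)
        assert T[2, 0] == pytest.approx(0.25)


class TestRandomWalkRestart:
    def test_gamma_one_returns_seed_vector(self, path_network):
        sv = random_walk_restart({"a"}, path_network, PropagationConfig(gamma=1.0))
        assert sv.scores == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_path_matches_linear_solve(self, path_network):
        cfg = PropagationConfig(gamma=0.5)
        sv = random_walk_restart({"a"}, path_network, cfg)
        oracle = solve_stationary_oracle({"a"}, path_network, gamma=0.5)
        for g in sv.scores:
            assert sv.scores[g] == pytest.approx(oracle.scores[g], abs=1e-10)
        # independent dense-solve cross-check, written out by hand
        T = np.array([[0, 0.5, 0], [1, 0, 1], [0, 0.5, 0]], dtype=float)
        p0 = np.array([1.0, 0, 0])
        expected = 0.5 * np.linalg.solve(np.eye(3) - 0.5 * T, p0)
        got = np.array([sv.scores[g] for g in path_network.nodes])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_disconnected_component_unreachable(self):
        net = GeneNetwork(["a", "b", "x", "y"], [("a", "b"), ("x", "y")])
        sv = random_walk_restart({"a"}, net, PropagationConfig())
        assert sv.scores["x"] == 0.0 and sv.scores["y"] == 0.0

    def test_off_network_seeds_reported(self, path_network):
        sv = random_walk_restart({"a", "ZZZ"}, path_network, PropagationConfig())
        assert sv.off_network_seeds == {"ZZZ"}
        assert sv.seed_set == {"a"}

    def test_no_seed_in_network_fatal(self, path_network):
        with pytest.raises(EmptySeedError, match="ZZZ"):
            random_walk_restart({"ZZZ"}, path_network, PropagationConfig())

    def test_nonconvergence_warns_but_returns(self, path_network):
        with pytest.warns(UserWarning, match="did not reach"):
            sv = random_walk_restart(
                {"a"}, path_network, PropagationConfig(gamma=0.3, max_iter=2)
            )
        assert sum(sv.scores.values()) == pytest.approx(1.0, abs=1e-9)
        assert not sv.converged

    def test_conservation_and_lower_bound(self, path_network):
        cfg = PropagationConfig(gamma=0.7)
        sv = random_walk_restart({"a", "b"}, path_network, cfg)
        assert sum(sv.scores.values()) == pytest.approx(1.0, abs=1e-9)
        for g, p0g in (("a", 0.5), ("b", 0.5), ("c", 0.0)):
            assert sv.scores[g] >= 0.7 * p0g - 1e-12

    def test_dangling_node_mass_conserved(self):
        net = GeneNetwork(["a", "b", "z"], [("a", "b")])
        sv = random_walk_restart({"a", "z"}, net, PropagationConfig(gamma=0.5))
        assert sum(sv.scores.values()) == pytest.approx(1.0, abs=1e-9)
        oracle = solve_stationary_oracle({"a", "z"}, net, gamma=0.5)
        for g in sv.scores:
            assert sv.scores[g] == pytest.approx(oracle.scores[g], abs=1e-10)

    def test_seed_symmetry_on_automorphic_graph(self):
        # 4-cycle: seeding opposite corners makes the other two equivalent
        net = GeneNetwork(["a", "b", "c", "d"], [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        sv = random_walk_restart({"a", "c"}, net, PropagationConfig(gamma=0.6))
        assert sv.scores["b"] == pytest.approx(sv.scores["d"], abs=1e-12)
        assert sv.scores["a"] == pytest.approx(sv.scores["c"], abs=1e-12)


class TestOracle:
    def test_gamma_one(self, path_network):
        sv = solve_stationary_oracle({"b"}, path_network, gamma=1.0)
        assert sv.scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_oracle_equivalence_100_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            net = random_connected_network(rng, n)
            seeds = set(rng.choice(net.nodes, size=int(rng.integers(1, max(2, n // 3))), replace=False))
            gamma = float(rng.uniform(0.2, 0.9))
            it = random_walk_restart(seeds, net, PropagationConfig(gamma=gamma))
            ex = solve_stationary_oracle(seeds, net, gamma=gamma)
            for g in net.nodes:
                assert abs(it.scores[g] - ex.scores[g]) < 1e-10

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        net = random_connected_network(rng, 12)
        perm = rng.permutation(net.nodes).tolist()
        edges = [(u, v, w) for (u, v), w in zip(
            [(net.nodes[i], net.nodes[j]) for i, j in zip(*net.adjacency().nonzero()) if i < j],
            [net.adjacency()[i, j] for i, j in zip(*net.adjacency().nonzero()) if i < j],
        )]
        net2 = GeneNetwork(perm, edges)
        sv1 = solve_stationary_oracle({net.nodes[0]}, net, gamma=0.7)
        sv2 = solve_stationary_oracle({net.nodes[0]}, net2, gamma=0.7)
        for g in net.nodes:
            assert sv1.scores[g] == pytest.approx(sv2.scores[g], abs=1e-12)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"gamma": 0.0}, {"gamma": 1.5}, {"tolerance": 0.0}, {"max_iter": 0}, {"norm": "l7"},
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(InvalidInputError):
            PropagationConfig(**kwargs)

    def test_empty_network_rejected(self):
        with pytest.raises(InvalidInputError):
            build_transition_matrix(GeneNetwork([], []))

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(InvalidInputError):
            GeneNetwork(["a", "a"], [])
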