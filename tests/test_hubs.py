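"""Tests of state-graph construction, signed Louvain and hub metrics."""

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from dfcstates import (centroid_to_graph, classify_hubs, consensus_partition,
                       louvain_signed, module_degree_z, participation_index,
                       signed_modularity)
from dfcstates.hubs import StateGraph, allegiance_matrix, hub_table


def _graph(adj, n=None):
    n = adj.shape[0] if n is None else n
    return StateGraph(adjacency=adj, node_ids=[f"n{i}" for i in range(n)],
                      subnetwork_labels=["net"] * n)


def _brute_force_modularity(adj, part, gamma=1.0):
    """Independent loop-level evaluation of the signed modularity."""
    P = np.where(adj > 0, adj, 0.0)
    N = np.where(adj < 0, -adj, 0.0)
    vp, vn = P.sum(), N.sum()

    def q(M, v):
        if v <= 0:
            return 0.0
        s = M.sum(axis=1)
        total = 0.0
        for i in range(adj.shape[0]):
            for j in range(adj.shape[0]):
                if part[i] == part[j]:
                    total += M[i, j] - gamma * s[i] * s[j] / v
        return total / v
    return q(P, vp) - (vn / (vp + vn)) * q(N, vn)


def _two_cliques(n_per=5, weight=1.0):
    n = 2 * n_per
    adj = np.zeros((n, n))
    for block in (slice(0, n_per), slice(n_per, n)):
        adj[block, block] = weight
    np.fill_diagonal(adj, 0.0)
    return adj


def _sbm(rng, n_blocks=4, per_block=10, p_in=0.9, p_out=0.05):
    n = n_blocks * per_block
    truth = np.repeat(np.arange(n_blocks), per_block)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if truth[i] == truth[j] else p_out
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1.0
    return adj, truth


class TestCentroidToGraph:
    def _windows(self, rng, W=100, C=6):
        E = C * (C - 1) // 2
        return 0.05 * rng.standard_normal((W, E))

    def test_zero_edge_zeroed(self):
        rng = np.random.default_rng(0)
        vals = self._windows(rng)
        vals[:, 0] = 0.0
        vals[:, 1] = 0.6  # one clearly non-zero edge keeps BH non-trivial
        g = centroid_to_graph(vals, [f"n{i}" for i in range(6)],
                              ["net"] * 6, alpha_fdr=0.05)
        iu = np.triu_indices(6, 1)
        assert g.adjacency[iu[0][0], iu[1][0]] == 0.0

    def test_constant_strong_edge_weight(self):
        rng = np.random.default_rng(1)
        vals = self._windows(rng)
        vals[:, 2] = 0.8
        g = centroid_to_graph(vals, [f"n{i}" for i in range(6)],
                              ["net"] * 6)
        iu = np.triu_indices(6, 1)
        w = g.adjacency[iu[0][2], iu[1][2]]
        np.testing.assert_allclose(w, np.arctanh(0.8), atol=1e-12)

    def test_null_edges_survival_bounded(self):
        """Independent noise edges: surviving fraction obeys the FDR level."""
        rng = np.random.default_rng(2)
        C, W = 20, 60
        E = C * (C - 1) // 2
        vals = 0.1 * rng.standard_normal((W, E))
        g = centroid_to_graph(vals, [f"n{i}" for i in range(C)],
                              ["net"] * C, alpha_fdr=0.05)
        iu = np.triu_indices(C, 1)
        frac = np.mean(g.adjacency[iu] != 0)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / E)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            centroid_to_graph(np.zeros((5, 15)),
                              [f"n{i}" for i in range(6)], ["net"] * 6)


class TestLouvain:
    def test_two_cliques_closed_form(self):
        adj = _two_cliques()
        part, Q = louvain_signed(adj, gamma=1.0, seed=0)
        assert len(np.unique(part)) == 2
        assert np.unique(part[:5]).size == 1 and np.unique(part[5:]).size == 1
        assert abs(Q - 0.5) < 1e-12

    def test_uniform_complete_graph_single_module(self):
        n = 8
        adj = np.ones((n, n)) - np.eye(n)
        part, Q = louvain_signed(adj, gamma=1.0, seed=0)
        assert np.unique(part).size == 1
        assert abs(Q) < 1e-12

    def test_planted_sbm_recovery(self):
        adj, truth = _sbm(np.random.default_rng(3))
        part, Q = louvain_signed(adj, gamma=1.0, seed=1)
        assert normalized_mutual_info_score(truth, part) == 1.0

    def test_q_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        adj = rng.standard_normal((15, 15))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        part, Q = louvain_signed(adj, gamma=1.0, seed=2)
        assert abs(Q - _brute_force_modularity(adj, part)) < 1e-10

    def test_gamma_scales_both_null_terms(self):
        rng = np.random.default_rng(5)
        adj = rng.standard_normal((12, 12))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        part = rng.integers(0, 3, size=12)
        for gamma in (0.5, 1.0, 2.0):
            assert abs(signed_modularity(adj, part, gamma)
                       - _brute_force_modularity(adj, part, gamma)) < 1e-10

    def test_all_zero_graph(self):
        part, Q = louvain_signed(np.zeros((6, 6)), seed=0)
        assert np.unique(part).size == 1
        assert Q == 0.0

    def test_deterministic_given_seed(self):
        adj, _ = _sbm(np.random.default_rng(6), p_in=0.6, p_out=0.2)
        a = louvain_signed(adj, seed=42)
        b = louvain_signed(adj, seed=42)
        np.testing.assert_array_equal(a[0], b[0])


class TestConsensus:
    def test_identical_runs_reproduced(self):
        adj = _two_cliques(6)
        part, T = consensus_partition(adj, n_runs=10, seed=0)
        single, _ = louvain_signed(adj, seed=0)
        assert normalized_mutual_info_score(part, single) == 1.0
        assert T.min() >= 0.0 and T.max() <= 1.0

    def test_allegiance_is_label_free(self):
        base = np.array([0, 0, 1, 1, 2, 2])
        permuted = np.array([2, 2, 0, 0, 1, 1])
        T = allegiance_matrix([base, permuted])
        np.testing.assert_array_equal(T, allegiance_matrix([base, base]))

    def test_idempotent_on_consensus(self):
        adj, truth = _sbm(np.random.default_rng(7))
        part, _ = consensus_partition(adj, n_runs=20, seed=1)
        # feed the consensus back through its own allegiance
        T = allegiance_matrix([part])
        np.fill_diagonal(T, 0.0)
        part2, _ = louvain_signed(T, gamma=1.0, seed=3)
        assert normalized_mutual_info_score(part, part2) == 1.0

    def test_planted_sbm_consensus(self):
        adj, truth = _sbm(np.random.default_rng(8))
        part, _ = consensus_partition(adj, n_runs=100, seed=2)
        assert normalized_mutual_info_score(truth, part) == 1.0


class TestHubMetrics:
    def test_equal_within_strength_gives_zero(self):
        adj = _two_cliques(4, weight=0.7)
        part = np.array([0] * 4 + [1] * 4)
        np.testing.assert_allclose(module_degree_z(adj, part), 0.0)

    def test_star_center_is_module_hub(self):
        n = 5
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1.0
        z = module_degree_z(adj, np.zeros(n, dtype=int))
        assert z[0] == z.max()
        assert z[0] > 1.0
        assert np.all(z[1:] < z[0])

    def test_singleton_module_zero(self):
        adj = _two_cliques(3)
        part = np.array([0, 0, 0, 1, 1, 2])
        z = module_degree_z(adj, part)
        assert z[5] == 0.0

    @pytest.mark.parametrize("n_modules,expected", [
        (1, 0.0), (2, 0.5), (3, 2.0 / 3.0)])
    def test_participation_even_split(self, n_modules, expected):
        n = 1 + n_modules
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1.0
        part = np.concatenate([[0], np.arange(n_modules)])
        P = participation_index(adj, part)
        assert abs(P[0] - expected) < 1e-12

    def test_matches_brute_force_formula(self):
        """P_i = 1 - sum_m (k_im/k_i)^2 evaluated by explicit loops."""
        rng = np.random.default_rng(9)
        adj = rng.standard_normal((20, 20))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        part = rng.integers(0, 4, size=20)
        P = participation_index(adj, part)
        Wp = np.where(adj > 0, adj, 0.0)
        for i in range(20):
            k_i = Wp[i].sum()
            if k_i == 0:
                assert P[i] == 0.0
                continue
            expected = 1.0
            for m in np.unique(part):
                k_im = Wp[i, part == m].sum()
                expected -= (k_im / k_i) ** 2
            assert abs(P[i] - expected) < 1e-12

    def test_isolated_node_zero(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        P = participation_index(adj, np.array([0, 0, 1, 1]))
        assert P[2] == 0.0 and P[3] == 0.0


class TestClassifyHubs:
    @pytest.mark.parametrize("z,P,role", [
        (1.5, 0.45, "connector"),     # e.g. a frontal control-network node
        (1.5, 0.21, "provincial"),    # e.g. a somatomotor node
        (0.5, 0.90, "non-hub"),
        (1.0, 0.90, "non-hub"),       # z boundary is strict
        (1.5, 0.30, "provincial"),    # P boundary goes to provincial
    ])
    def test_role_rules(self, z, P, role):
        assert classify_hubs(np.array([z]), np.array([P])) == [role]

    def test_roles_depend_only_on_z_and_p(self):
        rng = np.random.default_rng(10)
        z = rng.uniform(0, 2, 30)
        P = rng.uniform(0, 1, 30)
        assert classify_hubs(z, P) == classify_hubs(z.copy(), P.copy())


class TestHubTable:
    def test_full_characterization(self):
        adj = _two_cliques(6, weight=0.8)
        # add one cross-module connector node pattern
        adj[0, 6] = adj[6, 0] = 0.8
        g = _graph(adj)
        table = hub_table(g, n_runs=10, seed=0)
        assert set(table.columns) >= {"node", "subnetwork", "module",
                                      "module_degree_z",
                                      "participation_index", "role"}
        assert len(table) == 12
        assert set(table["role"]) <= {"connector", "provincial", "non-hub"}
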