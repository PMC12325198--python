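import numpy as np
import pytest

from oracles import (
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    random_graph,
)
from vrgamma.graphnet import (
    BinaryGraph,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    shortest_path_lengths,
    threshold_by_density,
)


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return BinaryGraph(a)


PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
TRIANGLE = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
STAR4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
K4 = graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
K5 = graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


class TestThresholding:
    def _sym_weights(self, n=59, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        return w

    def test_14pct_of_59_nodes_is_240_edges(self):
        g = threshold_by_density(self._sym_weights(), 0.14)
        assert g.n_edges == 240
        assert abs(g.density - 0.14) <= 1.0 / 1711

    def test_full_density_gives_complete_graph(self):
        g = threshold_by_density(self._sym_weights(), 1.0)
        assert g.n_edges == 59 * 58 // 2

    def test_diagonal_never_selected(self):
        g = threshold_by_density(self._sym_weights(), 0.14)
        assert not g.adjacency.diagonal().any()

    def test_all_equal_weights_tie_break_is_deterministic(self):
        w = np.ones((6, 6))
        g1 = threshold_by_density(w, 0.5)
        g2 = threshold_by_density(w, 0.5)
        assert g1.n_edges == round(0.5 * 15) == 8
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # lexicographically first upper-triangle pairs win
        rows, cols = np.triu_indices(6, 1)
        expected = set(zip(rows[:8], cols[:8]))
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(g1.adjacency, 1)))}
        assert got == expected

    def test_invalid_density_fatal(self):
        with pytest.raises(ValueError):
            threshold_by_density(self._sym_weights(), 0.0)


class TestWorkedExamples:
    def test_complete_graph_distances_all_one(self):
        d = shortest_path_lengths(K4)
        off = d[~np.eye(4, dtype=bool)]
        assert np.all(off == 1.0)

    def test_path_graph_two_hops(self):
        d = shortest_path_lengths(PATH3)
        assert d[0, 2] == 2.0

    def test_disconnected_pairs_infinite(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        d = shortest_path_lengths(g)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_nodal_efficiency_path3(self):
        assert np.allclose(nodal_efficiency(PATH3), [0.75, 1.0, 0.75])

    def test_nodal_efficiency_complete(self):
        assert np.allclose(nodal_efficiency(K4), 1.0)

    def test_isolated_node_has_zero_efficiency(self):
        g = graph_from_edges(4, [(0, 1), (0, 2)])
        assert nodal_efficiency(g)[3] == 0.0

    def test_global_efficiency_path3_is_5_6(self):
        assert global_efficiency(PATH3) == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_global_efficiency_degenerate_graphs(self):
        assert global_efficiency(K5) == 1.0
        empty = BinaryGraph(np.zeros((5, 5), dtype=bool))
        assert global_efficiency(empty) == 0.0

    def test_local_efficiency_triangle_is_one(self):
        assert np.allclose(local_efficiency(TRIANGLE), 1.0)

    def test_local_efficiency_star_center_is_zero(self):
        assert np.allclose(local_efficiency(STAR4), 0.0)

    def test_local_efficiency_complete_k5(self):
        assert np.allclose(local_efficiency(K5), 1.0)


class TestInvariants:
    def test_global_is_exact_mean_of_nodal(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = BinaryGraph(random_graph(10, 0.3, rng))
            assert global_efficiency(g) == nodal_efficiency(g).mean()

    def test_adding_an_edge_never_hurts(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = random_graph(9, 0.25, rng)
            free = np.argwhere(~a & ~np.eye(9, dtype=bool))
            free = free[free[:, 0] < free[:, 1]]
            if not len(free):
                continue
            i, j = free[rng.integers(len(free))]
            before = nodal_efficiency(BinaryGraph(a))
            a2 = a.copy()
            a2[i, j] = a2[j, i] = True
            after = nodal_efficiency(BinaryGraph(a2))
            assert np.all(after >= before - 1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            a = random_graph(n, float(rng.uniform(0.15, 0.7)), rng)
            g = BinaryGraph(a)
            assert np.allclose(nodal_efficiency(g), brute_nodal_efficiency(a), atol=1e-12)
            assert np.allclose(global_efficiency(g), brute_global_efficiency(a), atol=1e-12)
            assert np.allclose(local_efficiency(g), brute_local_efficiency(a), atol=1e-12)

    def test_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(10)
        for _ in range(10):
            a = random_graph(10, 0.35, rng)
            g = BinaryGraph(a)
            G = nx.from_numpy_array(a.astype(int))
            assert global_efficiency(g) == pytest.approx(nx.global_efficiency(G), abs=1e-12)
            assert local_efficiency(g).mean() == pytest.approx(
                nx.local_efficiency(G), abs=1e-12)

    def test_rejects_asymmetric_or_self_looped(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            BinaryGraph(a)
        b = np.eye(3, dtype=bool)
        with pytest.raises(ValueError, match="loops"):
            BinaryGraph(b)
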