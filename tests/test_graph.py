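import numpy as np
import pandas as pd
import pytest

from slgraph.graph import (
    BinaryGraph,
    aggregate_design,
    harmonic_aggregate,
    node_clustering,
    node_path_length,
    threshold_to_degree,
)


def worked_example_graph():
    """Seven-node illustration: X connected to A, B, C; A-B connected; C-D,
    D-E, C-F edges; distances from X: A=1, B=1, C=1, D=2, E=3, F=2."""
    names = ["X", "A", "B", "C", "D", "E", "F"]
    edges = [("X", "A"), ("X", "B"), ("X", "C"), ("A", "B"), ("A", "C"),
             ("C", "D"), ("D", "E"), ("C", "F")]
    n = len(names)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        i, j = names.index(a), names.index(b)
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adjacency=adj, K=2)


def random_graph(rng, n, p=0.3):
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    return BinaryGraph(adjacency=adj, K=1)


class TestWorkedExample:
    def test_clustering_of_x_is_two_thirds(self):
        g = worked_example_graph()
        assert node_clustering(g, 0) == pytest.approx(2.0 / 3.0)

    def test_path_length_of_x_is_ten_sixths(self):
        g = worked_example_graph()
        assert node_path_length(g, 0) == pytest.approx(10.0 / 6.0)


class TestThreshold:
    def test_edge_count_small(self):
        rng = np.random.default_rng(0)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        g = threshold_to_degree(m, 2)
        assert g.n_edges == 4

    def test_edge_count_full_scale(self):
        rng = np.random.default_rng(1)
        m = rng.random((61, 61))
        m = (m + m.T) / 2
        assert threshold_to_degree(m, 5).n_edges == 152

    def test_keeps_strongest_by_full_sort(self):
        rng = np.random.default_rng(2)
        n = 12
        m = rng.random((n, n))
        m = (m + m.T) / 2
        K = 4
        g = threshold_to_degree(m, K)
        iu = np.triu_indices(n, 1)
        order = np.argsort(m[iu])[::-1]
        expected = set(zip(iu[0][order[: (n * K) // 2]], iu[1][order[: (n * K) // 2]]))
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency, 1)))}
        assert got == expected

    def test_deterministic_under_ties(self):
        m = np.ones((6, 6))
        a = threshold_to_degree(m, 2).adjacency
        b = threshold_to_degree(m, 2).adjacency
        np.testing.assert_array_equal(a, b)
        assert a.sum() // 2 == 6

    @pytest.mark.parametrize("K", [0, 61, 100])
    def test_out_of_range_K_rejected(self, K):
        with pytest.raises(ValueError, match="K must"):
            threshold_to_degree(np.eye(61), K)


class TestNodeMetrics:
    def test_complete_graph(self):
        adj = ~np.eye(5, dtype=bool)
        g = BinaryGraph(adjacency=adj, K=4)
        for v in range(5):
            assert node_clustering(g, v) == 1.0
            assert node_path_length(g, v) == 1.0

    def test_disconnected_component_gives_infinite_path_length(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        g = BinaryGraph(adjacency=adj, K=1)
        assert node_path_length(g, 0) == np.inf

    def test_low_degree_nodes_have_zero_clustering(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        g = BinaryGraph(adjacency=adj, K=1)
        assert node_clustering(g, 0) == 0.0
        assert node_clustering(g, 2) == 0.0

    def test_matches_networkx_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            g = random_graph(rng, n, p=float(rng.uniform(0.1, 0.5)))
            G = nx.from_numpy_array(g.adjacency)
            nx_clust = nx.clustering(G)
            lengths = dict(nx.all_pairs_shortest_path_length(G))
            for v in range(n):
                assert node_clustering(g, v) == pytest.approx(nx_clust[v])
                d = lengths[v]
                if len(d) < n:
                    expected = np.inf
                else:
                    expected = sum(d[u] for u in range(n) if u != v) / (n - 1)
                assert node_path_length(g, v) == pytest.approx(expected)

    def test_adding_edge_never_increases_path_length(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_graph(rng, 12, p=0.3)
            free = np.argwhere(~g.adjacency & ~np.eye(12, dtype=bool))
            if len(free) == 0:
                continue
            i, j = free[rng.integers(len(free))]
            adj2 = g.adjacency.copy()
            adj2[i, j] = adj2[j, i] = True
            g2 = BinaryGraph(adjacency=adj2, K=g.K)
            for v in range(12):
                assert node_path_length(g2, v) <= node_path_length(g, v)


class TestHarmonicAggregate:
    def test_constant(self):
        assert harmonic_aggregate([2.0, 2.0, 2.0]) == pytest.approx(2.0)

    def test_infinity_contributes_zero_reciprocal(self):
        assert harmonic_aggregate([1.0, np.inf]) == pytest.approx(2.0)

    def test_all_infinite_stays_infinite(self):
        assert harmonic_aggregate([np.inf, np.inf]) == np.inf

    def test_matches_direct_formula(self, rng):
        v = rng.uniform(0.5, 4.0, size=8)
        assert harmonic_aggregate(v) == pytest.approx(len(v) / np.sum(1.0 / v))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            harmonic_aggregate([1.0, 0.0])


def toy_table(values):
    rows = []
    for (subj, cond, sess, ep), (c, l) in values.items():
        for node in (0,):
            rows.append(
                {"band": "alpha", "K": 4, "subject": subj, "condition": cond,
                 "session": sess, "epoch": ep, "node": node, "C": c, "L": l}
            )
    return pd.DataFrame(rows)


class TestAggregateDesign:
    def test_constant_table_unchanged(self):
        vals = {
            (s, c, sess, ep): (0.5, 2.0)
            for s in ("S1", "S2") for c in ("NS", "TSD")
            for sess in (0, 1) for ep in (0, 1)
        }
        out = aggregate_design(toy_table(vals))
        assert np.allclose(out["C"], 0.5)
        assert np.allclose(out["L"], 2.0)

    def test_two_stage_hand_computation(self):
        vals = {
            ("S1", "NS", 0, 0): (0.5, 2.0), ("S1", "NS", 0, 1): (0.25, 4.0),
            ("S1", "NS", 1, 0): (0.5, 1.0), ("S1", "NS", 1, 1): (0.5, 1.0),
            ("S1", "TSD", 0, 0): (0.1, 3.0), ("S1", "TSD", 0, 1): (0.1, 3.0),
            ("S1", "TSD", 1, 0): (0.1, 3.0), ("S1", "TSD", 1, 1): (0.1, 3.0),
            ("S2", "NS", 0, 0): (0.5, 2.0), ("S2", "NS", 0, 1): (0.5, 2.0),
            ("S2", "NS", 1, 0): (0.5, 2.0), ("S2", "NS", 1, 1): (0.5, 2.0),
            ("S2", "TSD", 0, 0): (0.2, 5.0), ("S2", "TSD", 0, 1): (0.2, 5.0),
            ("S2", "TSD", 1, 0): (0.2, 5.0), ("S2", "TSD", 1, 1): (0.2, 5.0),
        }
        out = aggregate_design(toy_table(vals)).set_index(["subject", "condition"])
        # S1 NS epochs: harmonic(0.5, 0.25) = 1/3; sessions harmonic(1/3, 0.5) = 0.4
        assert out.loc[("S1", "NS"), "C"] == pytest.approx(0.4)
        # S1 NS L: harmonic(2, 4) = 8/3; harmonic(8/3, 1) = 16/11
        assert out.loc[("S1", "NS"), "L"] == pytest.approx(16.0 / 11.0)

    def test_infinite_epoch_yields_finite_aggregate(self):
        vals = {
            ("S1", c, 0, ep): (0.5, np.inf if (c, ep) == ("NS", 0) else 2.0)
            for c in ("NS", "TSD") for ep in range(4)
        }
        vals[("S2", "NS", 0, 0)] = (0.5, 2.0)
        for c in ("NS", "TSD"):
            for ep in range(4):
                vals.setdefault(("S2", c, 0, ep), (0.5, 2.0))
        out = aggregate_design(toy_table(vals)).set_index(["subject", "condition"])
        l = out.loc[("S1", "NS"), "L"]
        assert np.isfinite(l)
        assert l == pytest.approx(4.0 / (3.0 / 2.0))  # 1/inf := 0

    def test_epoch_permutation_invariance(self, rng):
        base = {}
        for s in ("S1", "S2"):
            for c in ("NS", "TSD"):
                cs = rng.uniform(0.1, 0.9, 4)
                ls = rng.uniform(1.0, 4.0, 4)
                for ep in range(4):
                    base[(s, c, 0, ep)] = (cs[ep], ls[ep])
        out1 = aggregate_design(toy_table(base))
        shuffled = {(s, c, sess, 3 - ep): v for (s, c, sess, ep), v in base.items()}
        out2 = aggregate_design(toy_table(shuffled))
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_cell_rejected(self):
        vals = {
            ("S1", "NS", 0, 0): (0.5, 2.0), ("S1", "NS", 0, 1): (0.5, 2.0),
            ("S1", "TSD", 0, 0): (0.5, 2.0),  # TSD missing epoch 1
        }
        with pytest.raises(ValueError, match="missing"):
            aggregate_design(toy_table(vals))

    def test_zero_clustering_floored_with_warning(self):
        vals = {
            (s, c, 0, ep): (0.0 if ep == 0 else 0.5, 2.0)
            for s in ("S1",) for c in ("NS", "TSD") for ep in (0, 1)
        }
        with pytest.warns(UserWarning, match="floored"):
            out = aggregate_design(toy_table(vals))
        assert (out["C"] > 0).all()
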