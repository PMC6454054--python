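import numpy as np
import pandas as pd
import pytest
import networkx as nx

from latidyn.core_io import OtuTable
from latidyn.conet import (
    CoNetwork,
    build_network,
    core_otus,
    correlation_matrix,
    network_topology,
    node_topology,
    select_threshold,
)


def net_from_edges(edges, nodes=None):
    nodes = nodes or sorted({v for e in edges for v in e[:2]})
    return CoNetwork(
        nodes=list(nodes),
        edges=[(a, b, w) for a, b, *rest in [(e + (1.0,))[:3] for e in edges]
               for w in [rest[0] if rest else 1.0]][: len(edges)],
        threshold=0.5,
    )


def simple_net(edges):
    nodes = sorted({v for a, b in edges for v in (a, b)})
    return CoNetwork(nodes=nodes, edges=[(a, b, 1.0) for a, b in edges], threshold=0.5)


class TestCoreOtus:
    def _table(self, presence_counts, n_samples=60):
        rng = np.random.default_rng(0)
        cols = {}
        for j, k in enumerate(presence_counts):
            col = np.zeros(n_samples, dtype=int)
            col[rng.choice(n_samples, size=k, replace=False)] = 5
            cols[f"o{j}"] = col
        return OtuTable(pd.DataFrame(cols, index=[f"s{i}" for i in range(n_samples)]))

    def test_strictly_greater_than_half(self):
        table = self._table([31, 30, 60])
        core = core_otus(table, 0.5)
        assert core.otu_ids == ["o0", "o2"]  # 31/60 kept, 30/60 dropped

    def test_threshold_zero_keeps_everything_present(self):
        table = self._table([1, 10, 60])
        assert core_otus(table, 0.0).n_otus == 3

    def test_empty_core_advises(self):
        table = self._table([1, 2])
        with pytest.raises(ValueError, match="threshold"):
            core_otus(table, 0.9)


class TestCorrelationMatrix:
    def test_duplicate_profile_and_opposite_profile(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 50, size=8)
        opposite = base.max() + base.min() - base  # exactly anti-linear
        df = pd.DataFrame({"a": base, "b": base * 2, "c": opposite},
                          index=[f"s{i}" for i in range(8)])
        # bypass compositional closure: feed counts with constant row sums
        df["pad"] = 500 - df.sum(axis=1)
        corr = correlation_matrix(OtuTable(df))
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 80, size=(6, 5))
        table = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(6)],
            columns=[f"o{j}" for j in range(5)],
        ))
        corr = correlation_matrix(table)
        rel = counts / counts.sum(axis=1, keepdims=True)
        for i in range(5):
            for j in range(5):
                x, y = rel[:, i], rel[:, j]
                expected = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_otu_flagged(self):
        df = pd.DataFrame(
            {"a": [1, 2, 3, 4, 5], "b": [2, 2, 2, 2, 2], "pad": [50, 49, 48, 47, 46]},
            index=[f"s{i}" for i in range(5)],
        )
        df["pad"] = 100 - df[["a", "b"]].sum(axis=1)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(OtuTable(df))
        assert corr.loc["a", "b"] == 0.0
        assert corr.loc["b", "b"] == 1.0


class TestBuildNetwork:
    def _corr(self, values):
        ids = [f"o{i}" for i in range(values.shape[0])]
        return pd.DataFrame(values, index=ids, columns=ids)

    def test_threshold_boundary_and_sign(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.79
        c[0, 2] = c[2, 0] = -0.85
        net = build_network(self._corr(c), 0.8)
        assert net.n_edges == 1
        assert net.edges[0][2] == pytest.approx(-0.85)
        assert net.n_negative_edges == 1

    def test_complete_graph_edge_count(self):
        c = np.full((4, 4), 0.9)
        np.fill_diagonal(c, 1.0)
        net = build_network(self._corr(c), 0.5)
        assert net.n_edges == 6  # n(n-1)/2

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(-1, 1, size=(10, 10))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            edges = {(a, b) for a, b, _ in build_network(self._corr(c), t).edges}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestNodeTopology:
    def test_path_graph_by_hand(self):
        topo = node_topology(simple_net([("A", "B"), ("B", "C")]))
        assert topo.loc["B", "degree"] == 2
        assert topo.loc["B", "betweenness"] == pytest.approx(1.0)
        assert topo.loc["B", "stress"] == 1
        assert topo.loc["B", "clustering_coefficient"] == 0.0
        assert topo.loc["A", "betweenness"] == 0.0

    def test_triangle_symmetry(self):
        topo = node_topology(simple_net([("A", "B"), ("B", "C"), ("A", "C")]))
        assert (topo["clustering_coefficient"] == 1.0).all()
        assert (topo["betweenness"] == 0.0).all()

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            nodes = [str(v) for v in g.nodes]
            edges = [(str(a), str(b), 1.0) for a, b in g.edges]
            net = CoNetwork(nodes=nodes, edges=edges, threshold=0.5)
            topo = node_topology(net)
            nx_bet = nx.betweenness_centrality(g, normalized=False)
            nx_cc = nx.clustering(g)
            for v in g.nodes:
                assert topo.loc[str(v), "degree"] == g.degree[v]
                assert topo.loc[str(v), "betweenness"] == pytest.approx(
                    nx_bet[v], abs=1e-10
                )
                assert topo.loc[str(v), "clustering_coefficient"] == pytest.approx(
                    nx_cc[v], abs=1e-10
                )
                # stress oracle: enumerate geodesics through v
                stress = 0
                for s in g.nodes:
                    for t in g.nodes:
                        if s >= t or v in (s, t):
                            continue
                        try:
                            paths = list(nx.all_shortest_paths(g, s, t))
                        except nx.NetworkXNoPath:
                            continue
                        stress += sum(1 for p in paths if v in p[1:-1])
                assert topo.loc[str(v), "stress"] == stress


class TestNetworkTopology:
    def test_triangle(self):
        topo = network_topology(simple_net([("A", "B"), ("B", "C"), ("A", "C")]))
        assert topo.nodes_n == 3 and topo.links_n == 3
        assert topo.avgCC == pytest.approx(1.0)
        assert topo.GD == pytest.approx(1.0)
        assert topo.M <= 0
        assert topo.CB == 0.0

    def test_star_is_maximally_centralized(self):
        topo = network_topology(
            simple_net([("hub", leaf) for leaf in ("a", "b", "c", "d")])
        )
        assert topo.CB == pytest.approx(1.0)
        assert topo.CS == pytest.approx(1.0)
        assert topo.avgCC == 0.0  # trees have no triangles

    def test_disjoint_edges_gd_over_connected_pairs(self):
        topo = network_topology(simple_net([("a", "b"), ("c", "d")]))
        assert topo.GD == pytest.approx(1.0)

    def test_modularity_of_two_cliques_with_bridge(self):
        edges = [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                 ("b1", "b2"), ("b1", "b3"), ("b2", "b3"), ("a1", "b1")]
        topo = network_topology(simple_net(edges))
        g = nx.Graph([(a, b) for a, b in edges])
        expected = nx.community.modularity(
            g, [{"a1", "a2", "a3"}, {"b1", "b2", "b3"}]
        )
        assert topo.M == pytest.approx(expected, abs=1e-10)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            network_topology(CoNetwork(nodes=["a"], edges=[], threshold=0.5))


class TestSelectThreshold:
    def test_fixed_method_passthrough(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        thr, _ = select_threshold(corr, method="fixed", fixed_value=0.8)
        assert thr == 0.8

    def test_pure_noise_prunes_aggressively(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 40))  # 30 samples, 40 independent profiles
        corr = pd.DataFrame(np.corrcoef(x.T))
        thr, report = select_threshold(corr, method="rmt",
                                       grid=np.arange(0.3, 0.96, 0.05))
        assert thr >= 0.5

    def test_block_structure_preserved(self):
        n_blocks, size = 4, 10
        c = np.zeros((n_blocks * size, n_blocks * size))
        for b in range(n_blocks):
            sl = slice(b * size, (b + 1) * size)
            c[sl, sl] = 0.9
        np.fill_diagonal(c, 1.0)
        ids = [f"o{i}" for i in range(n_blocks * size)]
        corr = pd.DataFrame(c, index=ids, columns=ids)
        thr, _ = select_threshold(corr, method="rmt",
                                  grid=np.arange(0.3, 0.96, 0.05))
        assert thr <= 0.9
        net = build_network(corr, thr)
        g = nx.Graph([(a, b) for a, b, _ in net.edges])
        comps = list(nx.connected_components(g))
        assert len(comps) == n_blocks
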