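import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from multitroph import (
    Network,
    ProbabilityMatrix,
    ValidationError,
    compare_networks,
    correlation_network,
    network_metrics,
)

from _oracles import (
    max_modularity_bruteforce,
    mean_path_length_bruteforce,
    modularity_bruteforce,
    spearman_bruteforce,
)


def _prob(values, species=None):
    values = np.asarray(values, dtype=float)
    species = species or [f"sp{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])],
                      columns=species)
    return ProbabilityMatrix(df, "baseline")


def _net_from_edges(edges, universe):
    g = nx.Graph()
    g.add_nodes_from(universe)
    for a, b in edges:
        g.add_edge(a, b, rho=0.5, p=0.001, sign=1)
    return Network(g, "baseline", species_universe=list(universe))


class TestCorrelationNetwork:
    def test_identical_columns_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0.1, 0.9, 15)
        net = correlation_network(_prob(np.column_stack([col, col])))
        assert net.graph.has_edge("sp0", "sp1")
        edge = net.graph.edges["sp0", "sp1"]
        assert np.isclose(edge["rho"], 1.0)
        assert edge["sign"] == 1

    def test_reversed_columns_perfectly_anticorrelated(self):
        rng = np.random.default_rng(1)
        col = np.sort(rng.uniform(0.1, 0.9, 15))
        net = correlation_network(_prob(np.column_stack([col, 1 - col])))
        edge = net.graph.edges["sp0", "sp1"]
        assert np.isclose(edge["rho"], -1.0)
        assert edge["sign"] == -1

    def test_rho_and_p_match_bruteforce(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, size=(14, 4))
        vals[3, 0] = vals[5, 0]                 # inject a tie
        net = correlation_network(_prob(vals), alpha=0.999999)
        for a, b, d in net.graph.edges(data=True):
            i, j = int(a[2:]), int(b[2:])
            rho, p = spearman_bruteforce(vals[:, i], vals[:, j])
            assert np.isclose(d["rho"], rho, atol=1e-10)
            assert np.isclose(d["p"], p, atol=1e-10)

    def test_constant_column_pairs_skipped(self):
        rng = np.random.default_rng(3)
        vals = np.column_stack([np.full(12, 0.5), rng.uniform(0, 1, 12),
                                rng.uniform(0, 1, 12)])
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(_prob(vals), alpha=0.999999)
        assert all("sp0" not in e for e in net.edge_set())

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValidationError):
            correlation_network(_prob(np.random.default_rng(0).uniform(size=(5, 3))))


class TestNetworkMetrics:
    def test_complete_graph_on_four_nodes(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"sp{i}" for i in range(4)})
        net = Network(g, "baseline", species_universe=list(g.nodes))
        for a, b in g.edges:
            g.edges[a, b].update(rho=0.9, p=1e-4, sign=1)
        m = network_metrics(net)
        assert m.connectance == 1.0
        assert m.mean_path_length == 1.0
        assert np.isclose(m.modularity, 0.0, atol=1e-12)
        assert m.n_communities == 1

    def test_two_disjoint_triangles(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f")]
        net = _net_from_edges(edges, "abcdef")
        m = network_metrics(net)
        assert m.n_communities == 2
        assert np.isclose(m.modularity, 0.5, atol=1e-12)
        # oracle: Q of the exhaustively best partition
        assert np.isclose(m.modularity, max_modularity_bruteforce("abcdef", edges),
                          atol=1e-10)

    def test_path_graph_mean_distance(self):
        net = _net_from_edges([("a", "b"), ("b", "c")], "abc")
        m = network_metrics(net)
        assert np.isclose(m.mean_path_length, 4.0 / 3.0, atol=1e-12)
        assert np.isclose(m.mean_path_length,
                          mean_path_length_bruteforce("abc", [("a", "b"), ("b", "c")]),
                          atol=1e-12)

    def test_metrics_match_bruteforce_on_random_small_graphs(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            g = nx.gnp_random_graph(7, 0.45, seed=int(rng.integers(1000)))
            if g.number_of_edges() < 2:
                continue
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            for a, b in g.edges:
                g.edges[a, b].update(rho=0.5, p=0.001, sign=1)
            net = Network(g, "baseline", species_universe=list(g.nodes))
            m = network_metrics(net)
            used = [v for v in g.nodes if g.degree[v] > 0]
            edges = list(g.edges())
            assert np.isclose(m.mean_path_length,
                              mean_path_length_bruteforce(used, edges), atol=1e-10)
            assert m.connectance == g.number_of_edges() / (len(used) * (len(used) - 1) / 2)
            # the reported partition's Q must match the formula exactly and
            # never exceed the exhaustive optimum
            q_best = max_modularity_bruteforce(used, edges)
            assert m.modularity <= q_best + 1e-10

    def test_invariant_to_node_relabelling(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
        m1 = network_metrics(_net_from_edges(edges, "abcd"))
        relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
        edges2 = [(relabel[a], relabel[b]) for a, b in edges]
        m2 = network_metrics(_net_from_edges(edges2, "wxyz"))
        assert m1.connectance == m2.connectance
        assert np.isclose(m1.modularity, m2.modularity, atol=1e-12)

    def test_empty_network_reported_as_missing(self):
        net = _net_from_edges([], "abc")
        m = network_metrics(net)
        assert m.n_nodes == 0 and m.n_edges == 0
        assert m.mean_path_length is None and m.modularity is None


class TestCompareNetworks:
    def test_identical_networks(self):
        net = _net_from_edges([("a", "b"), ("b", "c")], "abc")
        ch = compare_networks(net, net)
        assert ch.counts == {"gained": 0, "lost": 0, "retained": 2, "sign_flipped": 0}

    def test_disjoint_edge_sets(self):
        ref = _net_from_edges([("a", "b")], "abcd")
        oth = _net_from_edges([("c", "d")], "abcd")
        ch = compare_networks(ref, oth)
        assert ch.counts["retained"] == 0
        assert ch.counts["gained"] == 1 and ch.counts["lost"] == 1

    def test_partial_overlap(self):
        ref = _net_from_edges([("a", "b"), ("b", "c")], "abcd")
        oth = _net_from_edges([("b", "c"), ("c", "d")], "abcd")
        ch = compare_networks(ref, oth)
        assert ch.counts == {"gained": 1, "lost": 1, "retained": 1, "sign_flipped": 0}
        assert ch.retained == [("b", "c")]

    def test_mismatched_universe_rejected(self):
        ref = _net_from_edges([("a", "b")], "ab")
        oth = _net_from_edges([("a", "b")], "abc")
        with pytest.raises(ValidationError):
            compare_networks(ref, oth)

    @given(st.sets(st.sampled_from([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"),
                                    ("b", "d"), ("c", "d")])),
           st.sets(st.sampled_from([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"),
                                    ("b", "d"), ("c", "d")])))
    def test_count_identities(self, ref_edges, oth_edges):
        ref = _net_from_edges(sorted(ref_edges), "abcd")
        oth = _net_from_edges(sorted(oth_edges), "abcd")
        ch = compare_networks(ref, oth)
        assert ch.counts["gained"] + ch.counts["retained"] == len(oth_edges)
        assert ch.counts["lost"] + ch.counts["retained"] == len(ref_edges)
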