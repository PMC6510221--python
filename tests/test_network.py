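import networkx as nx
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from assemblyscope import (
    OtuTable,
    build_network,
    cooccurrence_network,
    modularity_partition,
    node_roles,
    spearman_edge_screen,
    topology_metrics,
)
from assemblyscope.network import modularity_q


def monotone_table(n_samples=8):
    """Taxa monotone in relative abundance: column totals are constant, so
    counts and per-sample proportions share the same ranks."""
    s = np.arange(n_samples)
    data = {
        "up1": 10 + 10 * s,
        "up2": 6 + 6 * s,
        "up3": 4 + 4 * s,
        "down": 80 - 10 * s,
        "filler": 200 - 10 * s,
    }
    df = pd.DataFrame(data).T
    assert (df.sum(axis=0) == df.sum(axis=0).iloc[0]).all()
    df.columns = [f"s{i}" for i in range(n_samples)]
    return OtuTable(df)


class TestSpearmanEdgeScreen:
    def test_monotone_pairs_found_with_signs(self):
        edges = spearman_edge_screen(monotone_table(), prevalence_min=1)
        key = {frozenset((r.taxon_i, r.taxon_j)): r for r in edges.itertuples()}
        up_pair = key[frozenset(("up1", "up2"))]
        assert up_pair.rho == pytest.approx(1.0)
        assert up_pair.sign == "positive"
        anti = key[frozenset(("up1", "down"))]
        assert anti.rho == pytest.approx(-1.0)
        assert anti.sign == "negative"

    def test_bh_adjustment_matches_hand_computation(self):
        # (0.01, 0.02, 0.03, 0.04) -> all adjusted to 0.04
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_kept_edges_satisfy_both_criteria(self):
        edges = spearman_edge_screen(
            monotone_table(), rho_min=0.6, alpha=0.05, prevalence_min=1
        )
        assert (edges["rho"].abs() > 0.6).all()
        assert (edges["p_adj"] < 0.05).all()

    def test_lowering_rho_min_never_removes_edges(self):
        strict = spearman_edge_screen(monotone_table(), rho_min=0.9, prevalence_min=1)
        loose = spearman_edge_screen(monotone_table(), rho_min=0.6, prevalence_min=1)
        strict_pairs = {frozenset((r.taxon_i, r.taxon_j)) for r in strict.itertuples()}
        loose_pairs = {frozenset((r.taxon_i, r.taxon_j)) for r in loose.itertuples()}
        assert strict_pairs <= loose_pairs

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [2, 1], "s3": [1, 1]},
                          index=["a", "b"])
        with pytest.raises(ValueError):
            spearman_edge_screen(OtuTable(df))


def edges_df(pairs):
    return pd.DataFrame(
        [{"taxon_i": a, "taxon_j": b, "rho": r, "sign": "positive" if r > 0 else "negative"}
         for a, b, r in pairs]
    )


class TestBuildNetwork:
    def test_triangle_counts(self):
        g = build_network(edges_df([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_empty_edge_list(self):
        g = build_network(edges_df([]))
        assert g.number_of_nodes() == 0

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError):
            build_network(edges_df([("a", "b", 1), ("b", "a", 0.9)]))

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            build_network(edges_df([("a", "a", 1)]))


class TestModularity:
    def test_two_triangles_with_bridge(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)])
        partition, q = modularity_partition(g)
        assert len(set(partition.values())) == 2
        assert q == pytest.approx(5 / 14)

    def test_disconnected_triangles(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        partition, q = modularity_partition(g)
        assert q == pytest.approx(0.5)

    def test_single_clique_one_module_q_zero(self):
        g = nx.complete_graph(4)
        partition = {n: 0 for n in g.nodes}
        assert modularity_q(g, partition) == pytest.approx(0.0)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            modularity_partition(nx.Graph())


class TestTopologyMetrics:
    def test_triangle(self):
        g = nx.complete_graph(3)
        m = topology_metrics(g)
        assert m["avg_degree"] == pytest.approx(2.0)
        assert m["avg_clustering"] == pytest.approx(1.0)
        assert m["avg_path_length"] == pytest.approx(1.0)
        assert m["betweenness_centralization"] == pytest.approx(0.0)

    def test_path_graph_hand_values(self):
        g = nx.path_graph(["A", "B", "C"])
        m = topology_metrics(g)
        assert m["avg_clustering"] == pytest.approx(0.0)
        assert m["avg_path_length"] == pytest.approx(4 / 3)
        btw = nx.betweenness_centrality(g, normalized=True)
        assert btw["B"] == pytest.approx(1.0)
        assert m["betweenness_centralization"] == pytest.approx(1.0)

    def test_star_centralization_maximal(self):
        g = nx.star_graph(4)  # hub + 4 leaves
        m = topology_metrics(g)
        assert m["betweenness_centralization"] == pytest.approx(1.0)

    def test_disconnected_pairs_excluded_from_path_length(self):
        g = nx.Graph([(1, 2), (3, 4)])
        m = topology_metrics(g)
        assert m["avg_path_length"] == pytest.approx(1.0)


class TestNodeRoles:
    def test_all_edges_within_module_pi_zero(self):
        g = nx.complete_graph(4)
        partition = {n: 0 for n in g.nodes}
        roles = node_roles(g, partition)
        assert (roles["pi"] == 0).all()
        assert (roles["role"] == "peripheral").all()
        assert (roles["zi"] == 0).all()  # symmetric clique

    def test_split_degree_participation(self):
        # hub with degree 4 split 2/2 across two modules -> pi = 0.5
        g = nx.Graph([("h", "a1"), ("h", "a2"), ("h", "b1"), ("h", "b2"),
                      ("a1", "a2"), ("b1", "b2")])
        partition = {"h": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = node_roles(g, partition).set_index("taxon")
        assert roles.loc["h", "pi"] == pytest.approx(0.5)

    def test_role_partition_exhaustive(self):
        g = nx.karate_club_graph()
        partition, _ = modularity_partition(g)
        roles = node_roles(g, partition)
        assert set(roles["role"]) <= {
            "peripheral", "module_hub", "connector", "network_hub"
        }
        assert len(roles) == g.number_of_nodes()


class TestCooccurrenceNetwork:
    def test_end_to_end_on_monotone_table(self):
        net = cooccurrence_network(monotone_table(), prevalence_min=1)
        assert net.graph.number_of_edges() == len(net.edges)
        assert net.topology["n_vertices"] == net.graph.number_of_nodes()
        assert net.topology["avg_degree"] == pytest.approx(
            2 * net.topology["n_edges"] / net.topology["n_vertices"]
        )
        assert set(net.nodes["taxon"]) == set(net.graph.nodes)

    def test_graphml_round_trip(self, tmp_path):
        from assemblyscope.network import write_graphml

        net = cooccurrence_network(monotone_table(), prevalence_min=1)
        p = tmp_path / "net.graphml"
        write_graphml(net, p)
        back = nx.read_graphml(p)
        assert back.number_of_edges() == net.graph.number_of_edges()
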