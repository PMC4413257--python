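"""Graph metrics, motif enumeration, degree-preserving randomization."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from subtypenet._utils import DataConsistencyError
from subtypenet.netstats import (
    enumerate_motifs,
    edge_correlations,
    mean_abs_edge_correlation,
    motif_significance,
    network_metrics,
    randomize_network,
    skeletonize,
)


def typed_graph(edges, mirnas=()):
    g = nx.Graph()
    nodes = {n for e in edges for n in e}
    for n in nodes:
        g.add_node(n, node_type="miRNA" if n in mirnas else "gene")
    for u, v in edges:
        g.add_edge(u, v)
    for u, v in g.edges():
        t = sorted((g.nodes[u]["node_type"], g.nodes[v]["node_type"]))
        g.edges[u, v]["edge_class"] = f"{t[0]}-{t[1]}"
    return g


def brute_force_betweenness(g):
    """All-pairs shortest-path counting from scratch (test oracle)."""
    btw = dict.fromkeys(g, 0.0)
    nodes = list(g)
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            btw[v] += frac
    return btw


class TestSkeletonize:
    def test_antiparallel_edges_collapse(self):
        d = nx.DiGraph()
        d.add_node("a", node_type="gene")
        d.add_node("b", node_type="miRNA")
        d.add_edge("a", "b")
        d.add_edge("b", "a")
        g = skeletonize(d)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["edge_class"] == "gene-miRNA"

    def test_edge_class_symmetric_in_endpoints(self):
        d = nx.DiGraph()
        d.add_node("m", node_type="miRNA")
        d.add_node("g", node_type="gene")
        d.add_edge("m", "g")
        d2 = nx.DiGraph()
        d2.add_node("m", node_type="miRNA")
        d2.add_node("g", node_type="gene")
        d2.add_edge("g", "m")
        assert skeletonize(d).edges["m", "g"]["edge_class"] == \
            skeletonize(d2).edges["m", "g"]["edge_class"]


class TestMetrics:
    def test_path_graph_closed_forms(self):
        g = typed_graph([("a", "b"), ("b", "c"), ("c", "d")])
        m = network_metrics(g)
        assert m.density == pytest.approx(0.5)
        assert m.diameter == 3
        assert m.avg_clustering == 0.0
        assert m.avg_degree == pytest.approx(1.5)

    def test_complete_graph_closed_forms(self):
        g = typed_graph([(a, b) for a, b in combinations("abcd", 2)])
        m = network_metrics(g)
        assert m.density == pytest.approx(1.0)
        assert m.centralization == pytest.approx(0.0)
        assert m.char_path_length == pytest.approx(1.0)

    def test_betweenness_matches_brute_force(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.25,
                                    seed=int(rng.integers(10_000)))
            nx.set_node_attributes(g, "gene", "node_type")
            m = network_metrics(g)
            oracle = brute_force_betweenness(g)
            assert m.avg_betweenness == pytest.approx(
                np.mean(list(oracle.values())), abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(DataConsistencyError):
            network_metrics(nx.Graph())


class TestMotifEnumeration:
    def test_gene_triangle_is_one_pattern_instance(self):
        g = typed_graph([("a", "b"), ("b", "c"), ("a", "c")])
        counts, instances = enumerate_motifs(g)
        assert sum(counts.values()) == 1
        (key,) = counts
        assert "gene,gene,gene" in key
        assert instances[key] == [("a", "b", "c")]

    def test_mirna_star_is_one_typed_path(self):
        g = typed_graph([("m", "g1"), ("m", "g2")], mirnas={"m"})
        counts, _ = enumerate_motifs(g)
        assert sum(counts.values()) == 1
        (key,) = counts
        assert "miRNA" in key
        assert key.count("-") >= 2 and "edges=" in key
        # the two-edge star must be distinct from a typed triangle
        tri = typed_graph([("m", "g1"), ("m", "g2"), ("g1", "g2")],
                          mirnas={"m"})
        tri_counts, _ = enumerate_motifs(tri)
        assert set(tri_counts) != set(counts)

    def test_counts_equal_brute_force_triples(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(14, 0.2, seed=int(rng.integers(10_000)))
            for i, v in enumerate(g.nodes):
                g.nodes[v]["node_type"] = "miRNA" if i % 3 == 0 else "gene"
            counts, _ = enumerate_motifs(g)
            brute = 0
            for trip in combinations(g.nodes, 3):
                sub = g.subgraph(trip)
                if sub.number_of_edges() >= 2 and nx.is_connected(sub):
                    brute += 1
            assert sum(counts.values()) == brute

    def test_pattern_counts_invariant_under_relabeling(self, rng):
        g = nx.gnp_random_graph(10, 0.3, seed=4)
        nx.set_node_attributes(g, "gene", "node_type")
        counts, _ = enumerate_motifs(g)
        relabel = dict(zip(g.nodes, np.random.default_rng(0).permutation(
            [f"n{i}" for i in range(10)])))
        counts2, _ = enumerate_motifs(nx.relabel_nodes(g, relabel))
        assert counts == counts2

    def test_unsupported_motif_size_rejected(self):
        with pytest.raises(Exception):
            enumerate_motifs(nx.Graph(), k=4)


class TestRandomization:
    def test_degree_sequence_preserved_exactly(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=8)
        nx.set_node_attributes(g, "gene", "node_type")
        for u, v in g.edges():
            g.edges[u, v]["edge_class"] = "gene-gene"
        r = randomize_network(g, seed=1)
        assert dict(g.degree()) == dict(r.degree())

    def test_edge_class_totals_preserved(self, rng):
        g = typed_graph(
            [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g3"),
             ("g1", "g2"), ("g2", "g3"), ("m1", "m2"), ("m2", "m3"),
             ("m3", "g3"), ("m3", "g2")], mirnas={"m1", "m2", "m3"})
        r = randomize_network(g, seed=2)

        def class_counts(graph):
            out = {}
            for u, v in graph.edges():
                t = sorted((graph.nodes[u]["node_type"],
                            graph.nodes[v]["node_type"]))
                key = f"{t[0]}-{t[1]}"
                out[key] = out.get(key, 0) + 1
            return out
        assert class_counts(g) == class_counts(r)

    def test_two_disjoint_mixed_edges_admit_no_swap(self):
        g = typed_graph([("m1", "m2"), ("g1", "g2")], mirnas={"m1", "m2"})
        r = randomize_network(g, n_swaps=50, seed=0)
        assert set(map(frozenset, r.edges())) == \
            set(map(frozenset, g.edges()))

    def test_randomization_mixes_the_edge_set(self):
        g = nx.gnp_random_graph(25, 0.18, seed=5)
        nx.set_node_attributes(g, "gene", "node_type")
        r = randomize_network(g, seed=9)
        assert set(map(frozenset, r.edges())) != \
            set(map(frozenset, g.edges()))


class TestMotifSignificance:
    def test_planted_clique_triangles_enriched(self):
        g = nx.gnp_random_graph(30, 0.06, seed=2)
        clique = list(range(30, 35))
        g.add_edges_from(combinations(clique, 2))
        nx.set_node_attributes(g, "gene", "node_type")
        stats = motif_significance(g, n_random=100, seed=0)
        tri = [m for m in stats if "edges=0-1;0-2;1-2" in m.pattern]
        assert tri and tri[0].z >= 2.0 and tri[0].significant

    def test_instances_span_requirement(self):
        g = typed_graph([("a", "b"), ("b", "c")])
        stats = motif_significance(g, n_random=100, seed=0)
        # single path instance: observed=1 < min_count -> not significant
        assert all(not m.significant for m in stats)


class TestEdgeCorrelations:
    def test_identical_features_and_mean_definition(self, rng):
        import pandas as pd
        from conftest import two_group_labels
        labels = two_group_labels(10, 8)
        expr = pd.DataFrame(rng.standard_normal((3, 18)),
                            index=["a", "b", "c"], columns=labels.index)
        expr.loc["b"] = expr.loc["a"].to_numpy()
        g = typed_graph([("a", "b"), ("b", "c"), ("a", "c")])
        stats = motif_significance(g, n_random=100, seed=0)
        table = edge_correlations(stats, g, expr, labels)
        row = table[(table["node_a"] == "a") & (table["node_b"] == "b")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert mean_abs_edge_correlation(table) == pytest.approx(
            table["r"].abs().mean())
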