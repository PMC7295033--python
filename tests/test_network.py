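"""Graph thresholding, Markov Clustering, and the edge-count
resampling test.

MCL is cross-checked against an independent, deliberately plain
reimplementation (dense loop, no pruning) on the reference fixtures.
"""

import networkx as nx
import numpy as np
import pytest

from coipnet import edge_enrichment_permutation, mcl, threshold_graph
from coipnet.network import _mcl_matrix


def _clique_pair(bridge=True):
    graph = nx.Graph()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                graph.add_edge(f"n{base + i}", f"n{base + j}", score=1.0)
    if bridge:
        graph.add_edge("n0", "n4", score=1.0)
    return graph


def _reference_mcl(graph, inflation=2.0, iterations=200):
    """Straightforward MCL: no pruning, no per-component decomposition."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    size = len(nodes)
    a = np.zeros((size, size))
    for u, v, data in graph.edges(data=True):
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = data["score"]
    loop = a.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(a, loop)
    m = a / a.sum(axis=0)
    for _ in range(iterations):
        m = m @ m
        m = m**inflation
        m = m / m.sum(axis=0)
    clusters = []
    for i in range(size):
        if m[i, i] > 1e-6:
            members = frozenset(nodes[j] for j in np.nonzero(m[i] > 1e-6)[0])
            if members not in clusters:
                clusters.append(members)
    merged = []
    for c in clusters:
        hit = [m_ for m_ in merged if m_ & c]
        for m_ in hit:
            merged.remove(m_)
        merged.append(frozenset(set(c).union(*hit)) if hit else c)
    return set(merged)


class TestThresholdGraph:
    def test_cutoff_is_inclusive(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", score=0.90)
        graph.add_edge("b", "c", score=0.89)
        out = threshold_graph(graph, 0.9)
        assert set(out.edges) == {("a", "b")}
        assert set(out.nodes) == {"a", "b", "c"}  # isolated nodes retained

    def test_all_below_cutoff_leaves_edgeless_graph(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", score=0.2)
        out = threshold_graph(graph, 0.9)
        assert out.number_of_edges() == 0
        assert set(out.nodes) == {"a", "b"}

    def test_mixed_fixture_edge_count(self):
        rng = np.random.default_rng(2)
        graph = nx.Graph()
        scores = [0.95, 0.91, 0.97, 0.90] + list(rng.uniform(0.1, 0.89, 6))
        for i, s in enumerate(scores):
            graph.add_edge(f"u{i}", f"v{i}", score=float(s))
        assert threshold_graph(graph, 0.9).number_of_edges() == 4

    def test_invalid_cutoff_and_scores_rejected(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", score=0.5)
        with pytest.raises(ValueError):
            threshold_graph(graph, 1.5)
        bad = nx.Graph()
        bad.add_edge("a", "b", score=2.0)
        with pytest.raises(ValueError):
            threshold_graph(bad, 0.9)


class TestMCL:
    def test_bridged_cliques_split_into_two_clusters(self):
        assignment = mcl(_clique_pair(), min_size=2)
        expected = {
            frozenset({"n0", "n1", "n2", "n3"}),
            frozenset({"n4", "n5", "n6", "n7"}),
        }
        assert set(assignment.clusters) == expected
        assert assignment.unclustered == frozenset()
        assert set(assignment.clusters) == _reference_mcl(_clique_pair())

    def test_complete_graph_is_one_cluster(self):
        graph = nx.relabel_nodes(nx.complete_graph(8), lambda n: f"p{n}")
        nx.set_edge_attributes(graph, 1.0, "score")
        assignment = mcl(graph, min_size=2)
        assert [len(c) for c in assignment.clusters] == [8]
        assert set(assignment.clusters) == _reference_mcl(graph)

    def test_edgeless_graph_all_unclustered(self):
        graph = nx.Graph()
        graph.add_nodes_from(["a", "b", "c"])
        assignment = mcl(graph, min_size=7)
        assert assignment.clusters == []
        assert assignment.unclustered == frozenset({"a", "b", "c"})

    def test_min_size_relegates_small_clusters(self):
        assignment = mcl(_clique_pair(), min_size=7)
        assert assignment.clusters == []
        assert len(assignment.unclustered) == 8

    def test_partition_validity_and_permutation_invariance_on_random_graphs(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            graph = nx.gnp_random_graph(24, 0.15, seed=seed)
            graph = nx.relabel_nodes(graph, lambda n: f"node{n:02d}")
            for u, v in graph.edges:
                graph.edges[u, v]["score"] = float(rng.uniform(0.2, 1.0))
            assignment = mcl(graph, min_size=1)
            # partition: disjoint cover of all nodes
            seen = set(assignment.unclustered)
            total = len(seen)
            for cluster in assignment.clusters:
                total += len(cluster)
                seen |= cluster
            assert total == graph.number_of_nodes()
            assert seen == set(graph.nodes)
            # relabeling invariance
            mapping = {n: f"x{n}" for n in graph.nodes}
            relabeled = nx.relabel_nodes(graph, mapping)
            back = {
                frozenset(n[1:] for n in c)
                for c in mcl(relabeled, min_size=1).clusters
            }
            assert back == set(assignment.clusters)

    def test_converged_flow_matrix_is_column_stochastic(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.1, 1.0, (12, 12))
        a = (a + a.T) / 2
        m = _mcl_matrix(a, inflation=2.0, expansion=2, prune=1e-5, tol=1e-8, max_iter=200)
        np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_cluster_count_nondecreasing_in_inflation(self):
        counts = [
            len(mcl(_clique_pair(), inflation=i, min_size=1).clusters)
            for i in (1.5, 2.0, 3.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcl(nx.Graph())


class TestEdgeEnrichment:
    def test_whole_graph_subset_gives_p_one(self):
        graph = _clique_pair()
        result = edge_enrichment_permutation(graph, list(graph.nodes), n_perm=200, seed=0)
        assert result["p"] == 1.0
        assert result["observed"] == graph.number_of_edges()

    def test_zero_internal_edges_gives_p_one(self):
        graph = _clique_pair(bridge=False)
        result = edge_enrichment_permutation(graph, ["n0", "n4"], n_perm=200, seed=0)
        assert result["observed"] == 0
        assert result["p"] == 1.0

    def test_planted_modules_detected(self):
        rng = np.random.default_rng(1)
        graph = nx.gnm_random_graph(100, 150, seed=1)
        graph = nx.relabel_nodes(graph, lambda n: f"x{n}")
        nx.set_edge_attributes(graph, 0.5, "score")
        members = []
        for base in (0, 10):
            block = [f"x{base + i}" for i in range(10)]
            members += block
            for i in range(10):
                for j in range(i + 1, 10):
                    graph.add_edge(block[i], block[j], score=0.95)
        result = edge_enrichment_permutation(graph, members, n_perm=10000, seed=0)
        assert result["p"] <= 0.001
        assert result["observed"] > result["expected"]

    def test_oversized_or_foreign_subset_rejected(self):
        graph = _clique_pair()
        with pytest.raises(ValueError):
            edge_enrichment_permutation(graph, ["nope"], n_perm=200)
        with pytest.raises(ValueError):
            edge_enrichment_permutation(graph, list(graph.nodes), n_perm=10)
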