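"""Distance matrices, MSTs, k-MST unions and the two ranking schemes."""

import networkx as nx
import numpy as np
import pytest

from gsnet import (
    build_mst,
    count_disjoint_subtrees,
    hdp_ranking,
    mst_union,
    pairwise_euclidean,
    radial_ranking,
)
from gsnet.graphs import write_dot, write_graphml

from conftest import brute_force_mst_weight


class TestPairwiseEuclidean:
    @pytest.mark.parametrize(
        "values, i, j, expected",
        [
            ([[0.0, 3.0]], 0, 1, 3.0),  # 1-D distance
            ([[0.0, 3.0], [0.0, 4.0]], 0, 1, 5.0),  # 3-4-5 triangle
            ([[1.0, 1.0, 5.0], [2.0, 2.0, 7.0]], 0, 1, 0.0),  # identical columns
        ],
    )
    def test_known_distances(self, values, i, j, expected):
        d = pairwise_euclidean(np.asarray(values))
        assert d[i, j] == pytest.approx(expected)
        assert d[j, i] == pytest.approx(expected)

    def test_symmetric_zero_diagonal_and_triangle_inequality(self, rng):
        x = rng.normal(size=(7, 12))
        d = pairwise_euclidean(x)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_nonfinite_input_rejected(self):
        x = np.ones((2, 4))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match="row 1.*column 2"):
            pairwise_euclidean(x)


class TestBuildMst:
    def test_collinear_chain(self):
        # samples at 0, 1, 3 on a line: MST is the path with total weight 3
        d = pairwise_euclidean(np.array([[0.0, 1.0, 3.0]]))
        t = build_mst(d)
        assert set(map(frozenset, t.edges())) == {frozenset((0, 1)), frozenset((1, 2))}
        assert t.size(weight="weight") == pytest.approx(3.0)

    def test_two_samples_single_edge(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        t = build_mst(d)
        assert list(t.edges()) == [(0, 1)]

    def test_matches_exhaustive_minimum_over_all_spanning_trees(self, rng):
        # brute-force oracle: all 6^4 = 1296 Prüfer trees on 6 vertices
        for _ in range(5):
            d = pairwise_euclidean(rng.normal(size=(3, 6)))
            t = build_mst(d)
            assert t.size(weight="weight") == pytest.approx(brute_force_mst_weight(d))

    def test_deterministic_under_weight_ties(self):
        # duplicated samples create tied zero-weight edges; tree must be reproducible
        x = np.array([[0.0, 0.0, 1.0, 1.0, 2.0]])
        d = pairwise_euclidean(x)
        e1 = sorted(build_mst(d).edges())
        e2 = sorted(build_mst(d).edges())
        assert e1 == e2

    def test_degenerate_all_identical_samples_rejected(self):
        d = np.zeros((5, 5))
        with pytest.raises(ValueError, match="identical"):
            build_mst(d)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_mst(np.zeros((1, 1)))


class TestMstUnion:
    def test_order_one_equals_mst(self, rng):
        d = pairwise_euclidean(rng.normal(size=(4, 8)))
        assert sorted(mst_union(d, 1).edges()) == sorted(build_mst(d).edges())

    def test_edge_bound_and_contains_first_mst(self, rng):
        d = pairwise_euclidean(rng.normal(size=(3, 4)))
        u = mst_union(d, 2)
        assert u.number_of_edges() <= 2 * 3
        first = set(map(frozenset, build_mst(d).edges()))
        assert first <= set(map(frozenset, u.edges()))

    def test_second_mst_weight_at_least_first(self, rng):
        d = pairwise_euclidean(rng.normal(size=(3, 6)))
        first = build_mst(d)
        u2 = mst_union(d, 2)
        second_edges = set(map(frozenset, u2.edges())) - set(map(frozenset, first.edges()))
        w1 = first.size(weight="weight")
        w2 = sum(d[tuple(e)] for e in map(tuple, second_edges))
        assert w2 >= w1 - 1e-12
        # oracle: first MST weight is the brute-force minimum on this instance
        assert w1 == pytest.approx(brute_force_mst_weight(d))

    def test_unions_nested_in_k(self, rng):
        d = pairwise_euclidean(rng.normal(size=(4, 10)))
        prev = set()
        for k in range(1, 6):
            cur = set(map(frozenset, mst_union(d, k).edges()))
            assert prev <= cur
            prev = cur

    @pytest.mark.parametrize("k", [0, 6, -1])
    def test_order_out_of_range(self, k):
        with pytest.raises(ValueError, match=r"\[1, 5\]"):
            mst_union(np.zeros((4, 4)), k)


class TestCountDisjointSubtrees:
    @pytest.mark.parametrize(
        "labels, expected",
        [((1, 1, 2, 2), 2), ((1, 2, 1, 2), 4), ((1, 1, 1, 1), 1)],
    )
    def test_path_examples(self, labels, expected):
        path = nx.path_graph(4)
        assert count_disjoint_subtrees(path, np.array(labels)) == expected

    def test_equals_components_after_cross_edge_removal(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            labels = rng.integers(1, 3, size=n)
            r = count_disjoint_subtrees(tree, labels)
            cut = tree.copy()
            cut.remove_edges_from([e for e in tree.edges() if labels[e[0]] != labels[e[1]]])
            assert r == nx.number_connected_components(cut)
            assert 1 <= r <= n

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="labels"):
            count_disjoint_subtrees(nx.path_graph(4), np.array([1, 2]))


def _hdp_oracle(tree):
    """Independent recursive preorder: root at max weighted eccentricity,
    children in decreasing hop-height order, all ties to the smallest index."""
    dist = dict(nx.all_pairs_dijkstra_path_length(tree, weight="weight"))
    ecc = {v: max(dist[v].values()) for v in tree}
    root = min(tree, key=lambda v: (-ecc[v], v))

    def height(v, parent):
        hs = [height(c, v) for c in tree.neighbors(v) if c != parent]
        return 1 + max(hs, default=-1)

    order = []

    def visit(v, parent):
        order.append(v)
        for c in sorted(
            (c for c in tree.neighbors(v) if c != parent),
            key=lambda c: (-height(c, v), c),
        ):
            visit(c, v)

    visit(root, None)
    ranks = np.zeros(tree.number_of_nodes(), dtype=int)
    for r, v in enumerate(order, start=1):
        ranks[v] = r
    return ranks


def _radial_oracle(graph):
    """Independent BFS-layered ranking with the same tie-break."""
    ecc = nx.eccentricity(graph)
    root = min(graph, key=lambda v: (ecc[v], v))
    depth = nx.single_source_shortest_path_length(graph, root)
    wd = nx.single_source_dijkstra_path_length(graph, root, weight="weight")
    order = sorted(graph, key=lambda v: (depth[v], wd[v], v))
    ranks = np.zeros(graph.number_of_nodes(), dtype=int)
    for r, v in enumerate(order, start=1):
        ranks[v] = r
    return ranks


class TestHdpRanking:
    def test_path_preorder(self):
        path = nx.path_graph(3)
        nx.set_edge_attributes(path, 1.0, "weight")
        assert list(hdp_ranking(path)) == [1, 2, 3]

    def test_star_rooted_at_leaf(self):
        star = nx.star_graph(3)  # center 0, leaves 1..3
        nx.set_edge_attributes(star, 1.0, "weight")
        ranks = hdp_ranking(star)
        assert sorted(ranks) == [1, 2, 3, 4]
        assert ranks[1] == 1  # smallest-index leaf has eccentricity 2 > center's 1

    def test_matches_recursive_oracle_on_fixed_tree(self, fixed_seven_tree):
        assert np.array_equal(hdp_ranking(fixed_seven_tree), _hdp_oracle(fixed_seven_tree))

    def test_permutation_property_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 15))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            for u, v in tree.edges():
                tree.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
            ranks = hdp_ranking(tree)
            assert sorted(ranks) == list(range(1, n + 1))
            assert np.array_equal(ranks, _hdp_oracle(tree))


class TestRadialRanking:
    def test_path_centroid_root(self):
        path = nx.path_graph(3)
        nx.set_edge_attributes(path, 1.0, "weight")
        ranks = radial_ranking(path)
        assert ranks[1] == 1  # middle vertex has eccentricity 1
        assert sorted(ranks) == [1, 2, 3]

    def test_star_center_first(self):
        star = nx.star_graph(4)
        nx.set_edge_attributes(star, 1.0, "weight")
        assert radial_ranking(star)[0] == 1

    def test_matches_bfs_oracle(self, fixed_seven_tree, rng):
        assert np.array_equal(radial_ranking(fixed_seven_tree), _radial_oracle(fixed_seven_tree))
        for _ in range(25):
            n = int(rng.integers(3, 15))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            for u, v in tree.edges():
                tree.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
            ranks = radial_ranking(tree)
            assert sorted(ranks) == list(range(1, n + 1))
            assert np.array_equal(ranks, _radial_oracle(tree))

    def test_works_on_kmst_union_with_cycles(self, rng):
        d = pairwise_euclidean(rng.normal(size=(3, 8)))
        u = mst_union(d, 2)
        assert sorted(radial_ranking(u)) == list(range(1, 9))

    def test_disconnected_rejected(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            radial_ranking(g)


class TestGraphExport:
    def test_graphml_and_dot_round_trip_attributes(self, tmp_path, rng):
        d = pairwise_euclidean(rng.normal(size=(3, 5)))
        t = build_mst(d)
        labels = np.array([1, 1, 2, 2, 2])
        ranks = hdp_ranking(t)
        gml = tmp_path / "t.graphml"
        dot = tmp_path / "t.dot"
        write_graphml(t, gml, sample_ids=[f"s{i}" for i in range(5)], labels=labels, ranks=ranks)
        write_dot(t, dot, labels=labels)
        back = nx.read_graphml(gml)
        assert back.number_of_edges() == 4
        assert {data["label"] for _, data in back.nodes(data=True)} == {1, 2}
        text = dot.read_text()
        assert text.startswith("graph G {") and text.count("--") == 4
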