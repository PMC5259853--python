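"""Sample graphs: Euclidean distances, minimum spanning trees and rankings.

Every two-sample test in this package operates on the minimum spanning tree
(MST) of the complete graph over samples, with edge weights given by the
Euclidean distance between sample columns in R^p.  This module builds those
structures and derives the two vertex-ranking schemes used by the rank-based
tests:

* HDP ranking — a depth-first preorder of the tree rooted at a diameter
  endpoint ("high directed preorder"); sensitive to mean-shift alternatives.
* radial ranking — ranks increasing outward from the tree centroid;
  sensitive to scale (variance) alternatives.

Graphs are :class:`networkx.Graph` objects on integer vertices ``0..N-1``
with a ``weight`` attribute per edge.  Rank vectors are integer arrays where
``ranks[v]`` is the rank (1..N) of vertex ``v``.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "pairwise_euclidean",
    "build_mst",
    "mst_union",
    "count_disjoint_subtrees",
    "hdp_ranking",
    "radial_ranking",
    "write_graphml",
    "write_dot",
]


def pairwise_euclidean(expr) -> np.ndarray:
    """Euclidean distance matrix between sample columns.

    Parameters
    ----------
    expr : ExpressionMatrix or ndarray (p, N)

    Returns
    -------
    ndarray, shape (N, N)
        Symmetric matrix with zero diagonal; entry (i, j) is the distance
        between samples i and j in R^p.
    """
    values = getattr(expr, "values", expr)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D genes x samples array")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
    return squareform(pdist(values.T, metric="euclidean"))


def _sorted_edges(dist: np.ndarray):
    """All upper-triangle edges sorted by (weight, i, j).

    The lexicographic secondary key makes the MST a deterministic function
    of the distance matrix even when edge weights tie (e.g. duplicated
    samples), which permutation p-values require.
    """
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = dist[iu, ju]
    order = np.lexsort((ju, iu, w))
    return iu[order], ju[order], w[order]


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def _validate_dist(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    return dist


def build_mst(dist: np.ndarray) -> nx.Graph:
    """Minimum spanning tree of the complete graph defined by ``dist``.

    Kruskal's algorithm over edges sorted by (weight, i, j); the tree is a
    deterministic function of the distance matrix.  Raises if N < 2 or if
    all samples are identical (every distance zero), in which case any
    spanning tree is arbitrary and no statistic is informative.
    """
    dist = _validate_dist(dist)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to build a spanning tree")
    iu, ju = np.triu_indices(n, k=1)
    if np.all(dist[iu, ju] == 0):
        raise ValueError("all samples identical (all pairwise distances zero); MST undefined")
    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    uf = _UnionFind(n)
    n_edges = 0
    for i, j, w in zip(*_sorted_edges(dist)):
        if uf.union(int(i), int(j)):
            tree.add_edge(int(i), int(j), weight=float(w))
            n_edges += 1
            if n_edges == n - 1:
                break
    return tree


def mst_union(dist: np.ndarray, k: int) -> nx.Graph:
    """Union of the first ``k`` minimum spanning trees (1 <= k <= 5).

    MST_m is the MST of the graph with the edges of MST_1..MST_{m-1}
    removed.  When a residual graph is disconnected (possible for small N),
    the minimum spanning forest of its components is used for that order.
    The returned graph records ``k`` in ``G.graph['order']``.
    """
    if not 1 <= int(k) <= 5:
        raise ValueError(f"mst order must be in [1, 5], got {k}")
    k = int(k)
    dist = _validate_dist(dist)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    first = build_mst(dist)
    union = nx.Graph()
    union.add_nodes_from(range(n))
    union.add_edges_from(first.edges(data=True))
    used = set(frozenset(e) for e in first.edges())
    edges = _sorted_edges(dist)
    for _ in range(2, k + 1):
        uf = _UnionFind(n)
        forest_edges = []
        for i, j, w in zip(*edges):
            e = frozenset((int(i), int(j)))
            if e in used:
                continue
            if uf.union(int(i), int(j)):
                forest_edges.append((int(i), int(j), float(w)))
        for i, j, w in forest_edges:
            union.add_edge(i, j, weight=w)
            used.add(frozenset((i, j)))
    union.graph["order"] = k
    return union


def count_disjoint_subtrees(tree: nx.Graph, labels) -> int:
    """Runs statistic R: components left after deleting cross-group edges.

    Equals (number of edges whose endpoints carry different labels) + 1 for
    a tree.  Few components indicate that same-group samples cluster in the
    tree, i.e. the two groups separate in R^p.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != tree.number_of_nodes():
        raise ValueError(
            f"{labels.shape[0]} labels for {tree.number_of_nodes()} vertices"
        )
    cross = sum(1 for u, v in tree.edges() if labels[u] != labels[v])
    return cross + 1


def _subtree_heights(tree: nx.Graph, root: int) -> dict:
    """Height in hops of the subtree hanging below each vertex when rooted."""
    order = list(nx.dfs_postorder_nodes(tree, root))
    parent = dict(nx.dfs_predecessors(tree, root))
    height = {}
    for v in order:
        kids = [c for c in tree.neighbors(v) if parent.get(c) == v]
        height[v] = 1 + max((height[c] for c in kids), default=-1)
    return height


def hdp_ranking(tree: nx.Graph) -> np.ndarray:
    """High directed preorder ranks of the tree vertices.

    The tree is rooted at a vertex with the largest geodesic (weighted)
    eccentricity — one of the two endpoints of the longest path in the tree;
    ties go to the smallest vertex index.  Vertices are then ranked 1..N by
    depth-first preorder, visiting child subtrees in decreasing order of
    subtree height (hops), ties again by smallest index.  The root gets
    rank 1.  Leaves of long branches therefore get early blocks of ranks,
    which concentrates power toward mean-shift alternatives.
    """
    n = tree.number_of_nodes()
    ecc = nx.eccentricity(tree, weight="weight")
    root = min(range(n), key=lambda v: (-ecc[v], v))
    height = _subtree_heights(tree, root)
    ranks = np.zeros(n, dtype=int)
    seen = {root}
    stack = [root]
    rank = 0
    while stack:
        v = stack.pop()
        rank += 1
        ranks[v] = rank
        kids = [c for c in tree.neighbors(v) if c not in seen]
        seen.update(kids)
        # stack is LIFO: push in increasing (height desc, index asc) priority reversed
        kids.sort(key=lambda c: (-height[c], c), reverse=True)
        stack.extend(kids)
    return ranks


def radial_ranking(graph: nx.Graph) -> np.ndarray:
    """Ranks increasing radially from the graph centroid.

    The root is the vertex of minimum hop-count eccentricity (ties to the
    smallest index) and receives rank 1.  Remaining vertices are ranked in
    ascending order of (hop depth from root, weighted shortest-path distance
    from root, vertex index).  Works on trees and on k-MST unions, where
    depth is the unweighted shortest-path hop count.  Samples far out on
    branches — the signature of an inflated-variance group — receive the
    highest ranks.
    """
    n = graph.number_of_nodes()
    if not nx.is_connected(graph):
        raise ValueError("radial ranking requires a connected graph")
    hop_ecc = nx.eccentricity(graph)
    root = min(range(n), key=lambda v: (hop_ecc[v], v))
    depth = nx.single_source_shortest_path_length(graph, root)
    wdist = nx.single_source_dijkstra_path_length(graph, root, weight="weight")
    order = sorted(range(n), key=lambda v: (depth[v], wdist[v], v))
    ranks = np.zeros(n, dtype=int)
    for r, v in enumerate(order, start=1):
        ranks[v] = r
    return ranks


def _attach_attrs(graph: nx.Graph, sample_ids=None, labels=None, ranks=None) -> nx.Graph:
    g = graph.copy()
    for v in g.nodes():
        if sample_ids is not None:
            g.nodes[v]["sample_id"] = str(sample_ids[v])
        if labels is not None:
            g.nodes[v]["label"] = int(labels[v])
        if ranks is not None:
            g.nodes[v]["rank"] = int(ranks[v])
    return g


def write_graphml(graph: nx.Graph, path, sample_ids=None, labels=None, ranks=None):
    """Write a GraphML file with optional sample_id/label/rank vertex attributes."""
    nx.write_graphml(_attach_attrs(graph, sample_ids, labels, ranks), path)


def write_dot(graph: nx.Graph, path, sample_ids=None, labels=None, ranks=None):
    """Write a Graphviz DOT file with optional vertex attributes."""
    g = _attach_attrs(graph, sample_ids, labels, ranks)
    lines = ["graph G {"]
    for v in sorted(g.nodes()):
        attrs = g.nodes[v]
        if attrs:
            body = ", ".join(f'{k}="{attrs[k]}"' for k in sorted(attrs))
            lines.append(f'  {v} [{body}];')
        else:
            lines.append(f"  {v};")
    for u, v, data in sorted(g.edges(data=True)):
        w = data.get("weight")
        if w is not None:
            lines.append(f'  {u} -- {v} [weight="{w:.6g}"];')
        else:
            lines.append(f"  {u} -- {v};")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
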