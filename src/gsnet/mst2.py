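"""MST2 correlation-network summarization and hub-gene identification.

The MST2 of a gene-gene network is the union of its first minimum spanning
tree and the MST of the network with those edges removed.  On a correlation
network (edge weight 1 - |r_ij|, so strongly correlated genes are close) a
gene that correlates highly with the rest of the set sits centrally and
acquires a high MST2 degree, because the shortest connections of both trees
pass through it; weakly correlated genes end up peripheral with degree
typically 2.  The same construction applies to binary protein-protein
interaction (PPI) networks, using the adjacency matrix with unit edge
weights instead of correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .containers import ExpressionMatrix, check_labels
from .graphs import _UnionFind, write_dot, write_graphml
from .gsnca import GSNCAConfig, LowVarianceError, _low_sd_count, intergene_correlation

__all__ = [
    "CorrelationNetwork",
    "correlation_network",
    "adjacency_network",
    "find_mst2",
    "hub_genes",
    "mst2_two_condition",
    "plot_mst2_pair",
]


@dataclass(frozen=True)
class CorrelationNetwork:
    """Gene-gene network on a distance scale.

    ``weights[i, j]`` is the edge weight (1 - |r_ij| in correlation mode,
    1 for present edges in adjacency mode); in adjacency mode absent pairs
    carry no edge at all rather than a heavy one.
    """

    weights: np.ndarray
    gene_ids: tuple
    mode: str  # "correlation" | "adjacency"
    present: np.ndarray | None = None  # bool mask of existing edges (adjacency mode)

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    def edge_list(self):
        """Edges as (i, j, w) sorted by (weight, i, j) for deterministic MSTs."""
        n = self.n_genes
        iu, ju = np.triu_indices(n, k=1)
        if self.present is not None:
            keep = self.present[iu, ju]
            iu, ju = iu[keep], ju[keep]
        w = self.weights[iu, ju]
        order = np.lexsort((ju, iu, w))
        return list(zip(iu[order].tolist(), ju[order].tolist(), w[order].tolist()))


def correlation_network(expr_group, method: str = "pearson", gene_ids=None) -> CorrelationNetwork:
    """Build the 1 - |r| distance network from one condition's expression rows."""
    values = np.asarray(getattr(expr_group, "values", expr_group), dtype=float)
    if gene_ids is None:
        gene_ids = getattr(expr_group, "gene_ids", None) or tuple(
            f"g{i + 1}" for i in range(values.shape[0])
        )
    r = intergene_correlation(values, method=method, gene_ids=gene_ids)
    w = 1.0 - np.abs(r)
    np.fill_diagonal(w, 0.0)
    return CorrelationNetwork(np.clip(w, 0.0, 1.0), tuple(gene_ids), "correlation")


def adjacency_network(adj, gene_ids=None) -> CorrelationNetwork:
    """Wrap a symmetric binary adjacency matrix (PPI mode) with unit weights."""
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency matrix must be symmetric")
    if not np.all(np.isin(adj, (0, 1))):
        raise ValueError("adjacency matrix must be binary (0/1)")
    n = adj.shape[0]
    if gene_ids is None:
        gene_ids = tuple(f"g{i + 1}" for i in range(n))
    present = adj.astype(bool)
    np.fill_diagonal(present, False)
    return CorrelationNetwork(
        np.ones((n, n), dtype=float), tuple(gene_ids), "adjacency", present=present
    )


def _kruskal_forest(n: int, sorted_edges, excluded: set):
    """Minimum spanning forest over the non-excluded edges (deterministic)."""
    uf = _UnionFind(n)
    forest = []
    for i, j, w in sorted_edges:
        if frozenset((i, j)) in excluded:
            continue
        if uf.union(i, j):
            forest.append((i, j, w))
            if len(forest) == n - 1:
                break
    return forest


def find_mst2(net: CorrelationNetwork) -> nx.Graph:
    """Union of the first and second MSTs of a gene network.

    The second MST is the MST (spanning forest, if the residual network is
    disconnected) of the network with the first MST's edges removed.  The
    returned graph has gene ids as vertices, per-edge attributes ``weight``
    and ``mst`` (1 or 2), and the two trees are edge-disjoint by
    construction.
    """
    n = net.n_genes
    if n < 3:
        raise ValueError(f"MST2 needs at least 3 genes, got {n}")
    edges = net.edge_list()
    mst1 = _kruskal_forest(n, edges, set())
    if len(mst1) < n - 1:
        raise ValueError("network is disconnected; MST undefined")
    used = set(frozenset((i, j)) for i, j, _ in mst1)
    mst2 = _kruskal_forest(n, edges, used)
    g = nx.Graph()
    g.add_nodes_from(net.gene_ids)
    ids = net.gene_ids
    for rank, tree in ((1, mst1), (2, mst2)):
        for i, j, w in tree:
            g.add_edge(ids[i], ids[j], weight=float(w), mst=rank)
    g.graph["mode"] = net.mode
    return g


def hub_genes(g: nx.Graph, top: int | None = None):
    """Genes ranked by MST2 degree, descending; ties broken by gene id.

    The top-ranked gene is the candidate hub — the most strongly
    inter-correlated (potentially regulatory) member of the set.
    """
    ranked = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    if top is not None:
        ranked = ranked[:top]
    return ranked


def mst2_two_condition(
    expr,
    labels,
    config: GSNCAConfig | None = None,
    out_prefix: str | None = None,
):
    """One MST2 per condition, with consistent vertex identity.

    Applies the same standard-deviation guard as GSNCA when
    ``config.check_sd``.  With ``out_prefix`` writes
    ``<prefix>_group{1,2}.graphml``, ``.dot`` and ``<prefix>_hubs.tsv``
    (gene, degree in each condition).  Returns the two graphs.
    """
    config = config or GSNCAConfig()
    if not isinstance(expr, ExpressionMatrix):
        expr = ExpressionMatrix(np.asarray(expr, dtype=float))
    labels = check_labels(labels, expr.n_samples)
    if config.check_sd:
        n_bad = _low_sd_count(expr.values, labels, config.min_sd)
        if n_bad:
            raise LowVarianceError(n_bad, "the observed grouping")
    graphs = []
    for g in (1, 2):
        net = correlation_network(
            expr.values[:, labels == g], method=config.cor_method, gene_ids=expr.gene_ids
        )
        graphs.append(find_mst2(net))
    if out_prefix is not None:
        for g, graph in zip((1, 2), graphs):
            write_graphml(graph, f"{out_prefix}_group{g}.graphml")
            write_dot(graph, f"{out_prefix}_group{g}.dot")
        deg1 = dict(graphs[0].degree())
        deg2 = dict(graphs[1].degree())
        order = [g for g, _ in hub_genes(graphs[0])]
        with open(f"{out_prefix}_hubs.tsv", "w") as fh:
            fh.write("gene\tdegree_group1\tdegree_group2\n")
            for gene in order:
                fh.write(f"{gene}\t{deg1[gene]}\t{deg2[gene]}\n")
    return graphs[0], graphs[1]


def plot_mst2_pair(g1: nx.Graph, g2: nx.Graph, path: str, titles=("group 1", "group 2")):
    """Render the two MST2s side by side (cosmetic; layout is spring, seeded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(12, 6))
    for ax, g, title in zip(axes, (g1, g2), titles):
        pos = nx.spring_layout(g, seed=0)
        deg = dict(g.degree())
        nx.draw_networkx(
            g,
            pos=pos,
            ax=ax,
            node_size=[100 + 60 * deg[v] for v in g.nodes()],
            font_size=7,
            node_color="lightsteelblue",
        )
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
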