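"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest

from gsnet import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fixed_seven_tree():
    """A fixed 7-vertex weighted tree with a clear diameter and branches."""
    t = nx.Graph()
    t.add_weighted_edges_from(
        [(0, 1, 1.0), (1, 2, 2.0), (2, 3, 1.5), (1, 4, 0.5), (4, 5, 1.0), (2, 6, 0.25)]
    )
    return t


def brute_force_mst_weight(dist: np.ndarray) -> float:
    """Minimum total weight over all spanning trees, enumerated via Prüfer sequences.

    Every labeled tree on n vertices corresponds to exactly one Prüfer
    sequence of length n - 2 (Cayley), so the n^(n-2) sequences enumerate
    all spanning trees of the complete graph.
    """
    n = dist.shape[0]
    best = np.inf
    for seq in product(range(n), repeat=n - 2):
        tree = nx.from_prufer_sequence(list(seq))
        w = sum(dist[u, v] for u, v in tree.edges())
        best = min(best, w)
    return best


def all_label_vectors(n: int, n1: int):
    """Every two-group labeling of n samples with n1 group-1 members."""
    out = []
    for idx in combinations(range(n), n1):
        lab = np.full(n, 2, dtype=int)
        lab[list(idx)] = 1
        out.append(lab)
    return out


def make_expr(values) -> ExpressionMatrix:
    return ExpressionMatrix(np.asarray(values, dtype=float))
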