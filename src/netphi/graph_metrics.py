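"""Structural graph measures and partition-counting utilities.

Global efficiency (mean inverse shortest-path length) and Newman modularity
Q are the two structural quantities correlated against integrated
information in the network-structure sweep; the counting helpers quantify
how quickly exhaustive partition searches explode.
"""

from __future__ import annotations

import igraph as ig
import networkx as nx
import numpy as np

from .connectome_gen import WeightedGraph
from .exceptions import DegenerateGraphError, InvalidArgumentError

__all__ = [
    "global_efficiency",
    "modularity_newman",
    "laplacian_matrix",
    "count_bipartitions",
    "count_partitions",
]


def global_efficiency(graph: WeightedGraph) -> float:
    """E = (1/(n(n-1))) * sum_{i != j} 1/d(i, j) over binary hop distances.

    Unreachable pairs contribute 0 (their distance is infinite), which makes
    the measure well-defined on cut networks.
    """
    if graph.n < 2:
        raise InvalidArgumentError("global efficiency requires at least 2 nodes")
    G = nx.from_numpy_array((graph.weights > 0).astype(int))
    return float(nx.global_efficiency(G))


def modularity_newman(graph: WeightedGraph) -> tuple[float, np.ndarray]:
    """Newman spectral modularity: leading-eigenvector recursive bisection.

    Communities are detected by recursively splitting along the leading
    eigenvector of the modularity matrix until no split increases Q; the
    returned Q evaluates the standard modularity sum for the detected
    assignment.  Weighted graphs use their weights as adjacencies.
    """
    if not graph.is_connected():
        raise DegenerateGraphError(
            "modularity detection requires a connected graph; "
            "split components first"
        )
    W = graph.weights
    rows, cols = np.nonzero(np.triu(W))
    g = ig.Graph(
        n=graph.n,
        edges=list(zip(rows.tolist(), cols.tolist())),
    )
    weights = W[rows, cols].tolist()
    use_weights = not graph.binary
    clustering = g.community_leading_eigenvector(
        weights=weights if use_weights else None
    )
    labels = np.asarray(clustering.membership)
    communities = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
    G = nx.from_numpy_array(W)
    Q = float(
        nx.algorithms.community.modularity(
            G, communities, weight="weight" if use_weights else None
        )
    )
    return Q, labels


def laplacian_matrix(graph: WeightedGraph) -> np.ndarray:
    """Combinatorial Laplacian L = D - W (rows sum to zero, PSD)."""
    W = graph.weights
    return np.diag(W.sum(axis=1)) - W


def count_bipartitions(n: int) -> int:
    """Number of unordered bipartitions of n labelled nodes: 2^(n-1) - 1."""
    if n < 2:
        raise InvalidArgumentError("bipartitions require n >= 2")
    return 2 ** (n - 1) - 1


def count_partitions(n: int) -> int:
    """Bell number B(n): partitions of n labelled nodes into any number of
    non-empty groups, via the Bell-triangle recurrence (exact integers)."""
    if n < 1:
        raise InvalidArgumentError("partitions require n >= 1")
    row = [1]
    for _ in range(n - 1):
        nxt = [row[-1]]
        for value in row:
            nxt.append(nxt[-1] + value)
        row = nxt
    return row[-1]
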