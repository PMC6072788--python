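"""Global graph measures for binary and weighted structural covariance networks.

The five measures are the average strength (mean off-diagonal edge weight),
characteristic path length L, global efficiency E, clustering coefficient C
and transitivity T, each with binary and weighted variants:

    L = (1/n) sum_i [ sum_{j != i} d_ij / (n-1) ]
    E = (1/n) sum_i [ sum_{j != i} d_ij^{-1} / (n-1) ],  with inf^{-1} = 0
    C = (1/n) sum_i 2 t_i / (k_i (k_i - 1))
    T = sum_i 2 t_i / sum_i k_i (k_i - 1)

Binary distances count hops; weighted distances minimise the summed inverse
weight 1/w along the path (Dijkstra, f(0) = inf).  t_i is the triangle count
around node i for binary graphs, and for weighted graphs the geometric-mean
triangle intensity t_i = (1/2) sum_{j,h} (w_ij w_ih w_jh)^{1/3}.  The degree
k_i counts non-zero connections in both modes.  L is only meaningful when all
node pairs are reachable, which in this pipeline restricts it to weighted
(fully connected) networks; E handles disconnection via zero inverse distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import BinaryGraph, WeightedGraph
from .exceptions import DisconnectedGraphError, ParameterError

__all__ = [
    "DistanceMatrix",
    "NodalStats",
    "BINARY_METRICS",
    "WEIGHTED_METRICS",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_stats",
    "clustering_coefficient",
    "transitivity",
    "average_strength",
    "binary_distances",
    "weighted_distances",
    "path_length_from_distances",
    "efficiency_from_distances",
    "triangles_and_degrees",
    "clustering_from_nodal",
    "transitivity_from_nodal",
    "compute_metric",
]

#: Metrics defined for binary graphs in this pipeline (char. path length is
#: excluded: binary graphs are generally disconnected at these densities).
BINARY_METRICS = ("global_efficiency", "clustering", "transitivity")
#: Metrics defined for weighted graphs (fully connected in practice).
WEIGHTED_METRICS = (
    "average_strength",
    "char_path_length",
    "global_efficiency",
    "clustering",
    "transitivity",
)


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path distances; inf marks unreachable pairs."""

    distances: np.ndarray
    mode: str  # "binary" or "weighted"

    @property
    def n_nodes(self) -> int:
        return self.distances.shape[0]


@dataclass
class NodalStats:
    """Per-node degree k_i and triangle count / intensity t_i."""

    degree: np.ndarray
    triangles: np.ndarray
    mode: str


# ---------------------------------------------------------------- array core


def binary_distances(A: np.ndarray) -> np.ndarray:
    """Hop-count shortest paths of a binary adjacency matrix.

    Breadth-first search carried out by repeated matrix products: the
    reachable set at hop d is the support of R @ A.  These graphs have small
    diameter, so this beats a generic Dijkstra by a wide margin while giving
    identical distances.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reach = np.eye(n)
    d = 0
    while True:
        d += 1
        new_reach = ((reach @ A) > 0) | (reach > 0)
        new = new_reach & (reach == 0)
        if not new.any():
            break
        D[new] = d
        reach = new_reach.astype(float)
    return D


def weighted_distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge cost 1/w; absent edges (w=0) impassable.

    Distances equal Dijkstra's on the inverse-weight graph (f(0) = inf);
    computed all-pairs in one pass since the weight matrices here are dense.
    """
    W = np.asarray(W, dtype=float)
    with np.errstate(divide="ignore"):
        cost = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    # csgraph treats 0 entries of a dense matrix as "no edge"; costs are >= 1
    # here since w = |r| <= 1, so no true edge collides with the sentinel.
    return _csgraph_shortest_path(cost, method="FW", directed=False)


def path_length_from_distances(D: np.ndarray) -> float:
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    if np.isinf(off).any():
        raise DisconnectedGraphError(
            "characteristic path length undefined: graph has unreachable pairs"
        )
    return float(off.sum() / (n * (n - 1)))


def efficiency_from_distances(D: np.ndarray) -> float:
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(off), 0.0, 1.0 / np.where(off > 0, off, np.inf))
    return float(inv.sum() / (n * (n - 1)))


def triangles_and_degrees(M: np.ndarray, weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    """(t_i, k_i) for an adjacency (binary) or weight (weighted) matrix."""
    M = np.asarray(M, dtype=float)
    if weighted:
        if (M < 0).any():
            raise ParameterError("weighted triangle intensity requires w >= 0")
        k = (M > 0).sum(axis=1).astype(float)
        croot = np.cbrt(M)
        t = np.einsum("ij,jh,hi->i", croot, croot, croot) / 2.0
    else:
        k = M.sum(axis=1)
        t = np.einsum("ij,jh,hi->i", M, M, M) / 2.0
    return t, k


def clustering_from_nodal(t: np.ndarray, k: np.ndarray) -> float:
    denom = k * (k - 1)
    terms = np.where(k >= 2, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.mean())


def transitivity_from_nodal(t: np.ndarray, k: np.ndarray) -> float:
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        raise ParameterError("transitivity undefined: no node has degree >= 2")
    return float(2.0 * t.sum() / denom)


def average_strength_from_weights(W: np.ndarray) -> float:
    n = W.shape[0]
    return float(W.sum() / (n * (n - 1)))


# ------------------------------------------------------------- graph wrappers


def _matrix_and_mode(G: BinaryGraph | WeightedGraph) -> tuple[np.ndarray, str]:
    if isinstance(G, BinaryGraph):
        return G.adjacency, "binary"
    if isinstance(G, WeightedGraph):
        return G.weights, "weighted"
    raise ParameterError(f"expected BinaryGraph or WeightedGraph, got {type(G)!r}")


def shortest_paths(G: BinaryGraph | WeightedGraph) -> DistanceMatrix:
    M, mode = _matrix_and_mode(G)
    D = binary_distances(M) if mode == "binary" else weighted_distances(M)
    return DistanceMatrix(D, mode=mode)


def characteristic_path_length(D: DistanceMatrix) -> float:
    return path_length_from_distances(D.distances)


def global_efficiency(D: DistanceMatrix) -> float:
    return efficiency_from_distances(D.distances)


def nodal_stats(G: BinaryGraph | WeightedGraph) -> NodalStats:
    M, mode = _matrix_and_mode(G)
    t, k = triangles_and_degrees(M, weighted=(mode == "weighted"))
    return NodalStats(degree=k, triangles=t, mode=mode)


def clustering_coefficient(G: BinaryGraph | WeightedGraph) -> float:
    s = nodal_stats(G)
    return clustering_from_nodal(s.triangles, s.degree)


def transitivity(G: BinaryGraph | WeightedGraph) -> float:
    s = nodal_stats(G)
    return transitivity_from_nodal(s.triangles, s.degree)


def average_strength(W: WeightedGraph) -> float:
    if not isinstance(W, WeightedGraph):
        raise ParameterError("average strength is defined for weighted graphs")
    return average_strength_from_weights(W.weights)


def compute_metric(G: BinaryGraph | WeightedGraph, metric: str) -> float:
    """Dispatch a named metric on a graph (distances computed as needed)."""
    if metric == "average_strength":
        return average_strength(G)
    if metric == "char_path_length":
        return characteristic_path_length(shortest_paths(G))
    if metric == "global_efficiency":
        return global_efficiency(shortest_paths(G))
    if metric == "clustering":
        return clustering_coefficient(G)
    if metric == "transitivity":
        return transitivity(G)
    raise ParameterError(f"unknown metric {metric!r}")
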