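"""Structural covariance networks from residualized regional measures.

A group's connectivity matrix is the region-by-region Pearson correlation of
residual measures across its subjects.  Binary graphs keep the top fraction of
edges by signed correlation so that networks are compared at a common density;
weighted graphs use the absolute correlations as edge weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import ResidualTable
from .exceptions import NegativeEdgeWarning, ParameterError, ZeroVarianceError

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "WeightedGraph",
    "pearson_connectivity",
    "build_connectivity",
    "binarize_at_density",
    "to_weighted",
    "density_of",
    "edge_count_at_density",
    "edge_order",
    "adjacency_from_order",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson correlations, diagonal stored as 0."""

    values: np.ndarray
    region_labels: list[str]
    n_subjects: int
    group: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ParameterError("connectivity matrix must be symmetric")
        if self.n_subjects < 3:
            raise ParameterError("connectivity requires >= 3 subjects")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.region_labels, columns=self.region_labels
        ).to_csv(path)

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_regions, 1)
        labels = np.asarray(self.region_labels)
        return pd.DataFrame(
            {"region_i": labels[i], "region_j": labels[j], "value": self.values[i, j]}
        )


@dataclass
class BinaryGraph:
    """Undirected binary adjacency with a fixed edge count set by density."""

    adjacency: np.ndarray
    target_density: float
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if not np.array_equal(a, a.T):
            raise ParameterError("adjacency must be symmetric")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ParameterError("adjacency entries must be 0 or 1")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class WeightedGraph:
    """Undirected weighted graph with non-negative weights, zero diagonal."""

    weights: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ParameterError("weights must be symmetric")
        if (w < 0).any():
            raise ParameterError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def pearson_connectivity(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of a subjects x regions array.

    Diagonal is zeroed; a zero-variance column raises :class:`ZeroVarianceError`.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ParameterError("Pearson connectivity requires >= 3 subjects")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ZeroVarianceError(f"region at column {bad} has zero variance")
    r = np.corrcoef(X, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return r


def build_connectivity(
    residuals: ResidualTable, subject_subset=None, group: str | None = None
) -> ConnectivityMatrix:
    """Group connectivity matrix from a subject subset of the residual table.

    The subset (ids, or all subjects of ``group`` if omitted) must belong to a
    single group; structural covariance is a within-group construct.
    """
    if subject_subset is None:
        if group is None:
            raise ParameterError("provide subject_subset or group")
        subject_subset = residuals.ids(group)
    subject_subset = list(subject_subset)
    if len(subject_subset) < 3:
        raise ParameterError("subject subset must contain >= 3 subjects")
    indexed = residuals.data.set_index("subject_id")
    missing = [s for s in subject_subset if s not in indexed.index]
    if missing:
        raise ParameterError(f"unknown subject ids {missing[:5]}")
    rows = indexed.loc[subject_subset]
    groups = set(rows["group"])
    if len(groups) > 1:
        raise ParameterError(f"subset spans multiple groups {sorted(groups)}")
    X = rows[residuals.region_labels].to_numpy(dtype=float)
    try:
        r = pearson_connectivity(X)
    except ZeroVarianceError:
        sd = X.std(axis=0)
        bad = residuals.region_labels[int(np.flatnonzero(sd == 0)[0])]
        raise ZeroVarianceError(f"region {bad!r} has zero variance in the subset")
    return ConnectivityMatrix(
        r, residuals.region_labels, n_subjects=len(subject_subset), group=groups.pop()
    )


def edge_count_at_density(density: float, n_nodes: int) -> int:
    """Edge count m = round(density * n(n-1)/2), rounding half up."""
    pairs = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(density * pairs + 0.5))


def edge_order(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by descending signed correlation.

    Ties are broken by lexicographic (i, j) region index so binarization is
    deterministic and edge sets nest across densities.
    Returns (i_sorted, j_sorted, order) where order indexes the triu pairs.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    order = np.lexsort((ju, iu, -r[iu, ju]))
    return iu[order], ju[order], order


def binarize_at_density(C: ConnectivityMatrix, density: float) -> BinaryGraph:
    """Keep the strongest edges by signed correlation up to the target density.

    Warns if the retained set includes a non-positive correlation: at the
    densities of interest negative correlations are weaker than any retained
    positive one, so this signals an unusual correlation structure.
    """
    if not 0.0 < density < 1.0:
        raise ParameterError("density must lie in (0, 1)")
    n = C.n_regions
    m = edge_count_at_density(density, n)
    if m < 1:
        raise ParameterError("density too small: zero edges at this size")
    i_sorted, j_sorted, _ = edge_order(C.values)
    sel_i, sel_j = i_sorted[:m], j_sorted[:m]
    if C.values[sel_i[-1], sel_j[-1]] <= 0:
        warnings.warn(
            "binarization retained a non-positive correlation",
            NegativeEdgeWarning,
            stacklevel=2,
        )
    A = np.zeros((n, n))
    A[sel_i, sel_j] = 1.0
    A[sel_j, sel_i] = 1.0
    return BinaryGraph(A, target_density=density, region_labels=C.region_labels)


def adjacency_from_order(i_sorted: np.ndarray, j_sorted: np.ndarray, m: int, n: int) -> np.ndarray:
    """Adjacency matrix of the first m edges of a precomputed edge order."""
    A = np.zeros((n, n))
    A[i_sorted[:m], j_sorted[:m]] = 1.0
    A[j_sorted[:m], i_sorted[:m]] = 1.0
    return A


def to_weighted(C: ConnectivityMatrix) -> WeightedGraph:
    """Weighted graph with w_ij = |r_ij| (negative correlations magnitude-kept)."""
    return WeightedGraph(np.abs(C.values), region_labels=C.region_labels)


def density_of(G: BinaryGraph) -> float:
    """Realized density: edges / possible edges n(n-1)/2."""
    n = G.n_nodes
    return G.n_edges / (n * (n - 1) / 2)
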