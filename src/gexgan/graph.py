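"""Sample-level KNN graphs and parameter-free linear graph convolution.

Two KNN graphs are built over the training samples, one under Euclidean
distance and one under cosine distance; a single symmetric-normalized
propagation  D^(-1/2) (A + I) D^(-1/2) X  with identity activation and no
learned weights smooths each sample toward its neighbors.  The two smoothed
matrices X2 (Euclidean graph) and X3 (cosine graph), together with the raw
matrix X1, form the three training views fed to the three weight-tied
critics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import ExpressionDataset
from .errors import AlignmentError, DomainError, ParameterError

__all__ = [
    "NeighborGraph",
    "EnrichedViews",
    "build_knn_graph",
    "normalized_adjacency",
    "propagate",
    "enrich_views",
    "GraphEnricher",
]

METRICS = ("euclidean", "cosine")


@dataclass
class NeighborGraph:
    """Union-symmetrized KNN adjacency over samples.

    ``adjacency`` is binary and symmetric with a zero diagonal; every row
    has between k and n-1 ones.
    """

    adjacency: np.ndarray
    metric: str
    k: int

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ParameterError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ParameterError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ParameterError("adjacency must have a zero diagonal")
        if self.metric not in METRICS:
            raise ParameterError(f"metric must be one of {METRICS}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges (i, j) with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass
class EnrichedViews:
    """The triple of aligned training matrices (raw, Euclidean-smoothed,
    cosine-smoothed) with their shared per-sample labels."""

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    tissue: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        if not (self.x1.shape == self.x2.shape == self.x3.shape):
            raise AlignmentError("the three views must have identical shape")
        if len(self.tissue) != self.x1.shape[0]:
            raise AlignmentError("labels must align with view rows")

    @property
    def n_samples(self) -> int:
        return self.x1.shape[0]

    def view(self, index: int) -> np.ndarray:
        return (self.x1, self.x2, self.x3)[index - 1]


def _pairwise(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        if np.any(norms == 0):
            raise DomainError(
                "cosine distance undefined for an all-zero sample row"
            )
    return squareform(pdist(x, metric=metric))


def build_knn_graph(x: np.ndarray, k: int, metric: str) -> NeighborGraph:
    """Directed KNN relation (self excluded) symmetrized by union.

    Ties in neighbor rank are broken toward the lower sample index, making
    the construction deterministic.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if metric not in METRICS:
        raise ParameterError(f"metric must be one of {METRICS}")
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k={k} out of range [1, {n - 1}]")
    d = _pairwise(x, metric)
    np.fill_diagonal(d, np.inf)
    # stable argsort on distance: equal distances keep ascending index order
    order = np.argsort(d, axis=1, kind="stable")
    adjacency = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    adjacency[rows, cols] = 1.0
    adjacency = np.maximum(adjacency, adjacency.T)  # union symmetrization
    return NeighborGraph(adjacency=adjacency, metric=metric, k=k)


def normalized_adjacency(graph: NeighborGraph) -> np.ndarray:
    """Symmetric normalization D^(-1/2) (A + I) D^(-1/2).

    The added self-loop guarantees every degree is positive, so the result
    is always defined; it is symmetric and non-negative.
    """
    a_tilde = graph.adjacency + np.eye(graph.n_nodes)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def propagate(x: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """One linear graph convolution: normalized_adjacency(graph) @ x."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != graph.n_nodes:
        raise AlignmentError(
            f"matrix has {x.shape[0]} rows but graph has {graph.n_nodes} nodes"
        )
    return normalized_adjacency(graph) @ x


def enrich_views(train: ExpressionDataset, k: int = 5) -> EnrichedViews:
    """Build both KNN graphs from the raw training matrix and smooth it once
    over each, yielding the (X1, X2, X3) training views."""
    if train.n_samples < k + 1:
        raise ParameterError(
            f"need at least k+1={k + 1} samples, got {train.n_samples}"
        )
    x1 = train.values
    x2 = propagate(x1, build_knn_graph(x1, k, "euclidean"))
    x3 = propagate(x1, build_knn_graph(x1, k, "cosine"))
    return EnrichedViews(
        x1=x1, x2=x2, x3=x3, tissue=train.tissue, condition=train.condition
    )


class GraphEnricher(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: ``fit`` builds the two KNN graphs from a raw
    matrix, ``transform`` returns the propagated matrix for each metric."""

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: np.ndarray, y=None) -> "GraphEnricher":
        X = np.asarray(X, dtype=float)
        self.graphs_ = {
            metric: build_knn_graph(X, self.k, metric) for metric in METRICS
        }
        return self

    def transform(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {
            metric: propagate(np.asarray(X, dtype=float), graph)
            for metric, graph in self.graphs_.items()
        }
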