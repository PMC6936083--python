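"""k-nearest-neighbor graph and unnormalized Laplacian over sample columns.

Samples are the *columns* of the expression matrix X (features x samples).
The binary weight matrix follows the mutual-OR rule: an edge is present if
either endpoint is among the other's k nearest neighbors by Euclidean
distance, giving a symmetric W regardless of asymmetric neighborhoods.
The Laplacian is the unnormalized L = D - W with D the diagonal degree
matrix, the standard manifold-regularization operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ExpressionMatrix", "NeighborGraph", "build_knn_graph", "laplacian"]


@dataclass
class ExpressionMatrix:
    """Dense features-x-samples observation matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Expression values, rows are features, columns are samples. All
        entries must be finite.
    feature_ids : sequence of str, length m
    sample_ids : sequence of str, length n
    """

    values: np.ndarray
    feature_ids: Sequence[str] = field(default=None)
    sample_ids: Sequence[str] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need m >= 1 features and n >= 2 samples, got {m}x{n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{i}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{j}" for j in range(n)]
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class NeighborGraph:
    """Binary kNN graph: weights W, degrees D and Laplacian L = D - W."""

    W: np.ndarray
    D: np.ndarray
    L: np.ndarray
    k: int


def build_knn_graph(
    X: ExpressionMatrix | np.ndarray, k: int, metric: str = "euclidean"
) -> NeighborGraph:
    """Build the symmetric binary k-nearest-neighbor graph of the samples.

    w_ij = 1 iff x_i is among the k nearest neighbors of x_j *or* vice
    versa (distances between sample columns; a point never neighbors
    itself). Ties in distance are broken toward the lower sample index so
    the graph is deterministic; duplicate columns therefore pick each
    other first (distance 0).

    Parameters
    ----------
    X : ExpressionMatrix or ndarray (m, n)
    k : int
        Neighbor count, 1 <= k <= n-1.
    metric : str
        Distance metric passed to scipy ``cdist`` (default Euclidean).

    Returns
    -------
    NeighborGraph
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("input matrix contains non-finite entries")
    n = values.shape[1]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")

    pts = values.T  # samples as rows
    dist = cdist(pts, pts, metric=metric)
    np.fill_diagonal(dist, np.inf)  # self-exclusion
    # stable argsort: equal distances keep ascending index order
    order = np.argsort(dist, axis=1, kind="stable")
    neighbors = order[:, :k]  # row j = indices of N_k(x_j)

    W = np.zeros((n, n), dtype=float)
    rows = np.repeat(np.arange(n), k)
    W[rows, neighbors.ravel()] = 1.0
    W = np.maximum(W, W.T)  # mutual-OR rule
    np.fill_diagonal(W, 0.0)
    D, L = laplacian(W)
    return NeighborGraph(W=W, D=D, L=L, k=k)


def laplacian(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and unnormalized Laplacian L = D - W of a symmetric W."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.array_equal(W, W.T):
        raise ValueError("W must be symmetric")
    D = np.diag(W.sum(axis=1))
    L = D - W
    return D, L
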