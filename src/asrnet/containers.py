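"""Core data containers shared across the package.

The central objects are the node time-series matrix (time points x nodes),
the symmetric non-negative association matrix holding connection strengths,
and the ground-truth network used to score simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "GroundTruthNetwork",
    "AssociationMatrix",
    "CoefficientVector",
    "CoefficientMatrix",
    "ClusterAssignment",
]

_NORM_TOL = 1e-10


@dataclass
class TimeSeriesMatrix:
    """A d x n matrix of node time series (d time points, n nodes).

    Parameters
    ----------
    values
        Real matrix with one column per node.
    node_ids
        Node labels, length n. Defaults to ``n1..n<n>``.
    normalized
        True when every column has zero mean and unit l2 norm.
    """

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D array")
        d, n = self.values.shape
        if d < 2 or n < 2:
            raise ValueError(
                f"need at least 2 time points and 2 nodes, got shape {d}x{n}"
            )
        if not self.node_ids:
            self.node_ids = [f"n{i + 1}" for i in range(n)]
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match number of columns")
        if self.normalized:
            norms = np.linalg.norm(self.values, axis=0)
            if np.any(np.abs(norms - 1.0) > _NORM_TOL):
                raise ValueError("normalized flag set but columns are not unit norm")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruthNetwork:
    """Directed binary adjacency plus true cluster labels for simulated data.

    ``directed_adjacency[i, j] == 1`` means a directed link from node i to
    node j. Because estimated association matrices are undirected, scoring
    treats an unordered pair as truly connected when an edge exists in
    either direction.
    """

    directed_adjacency: np.ndarray
    true_labels: np.ndarray

    def __post_init__(self) -> None:
        self.directed_adjacency = np.asarray(self.directed_adjacency)
        self.true_labels = np.asarray(self.true_labels)
        a = self.directed_adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.true_labels.shape[0] != a.shape[0]:
            raise ValueError("labels length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.directed_adjacency.shape[0]

    @property
    def undirected_pairs(self) -> np.ndarray:
        """Boolean matrix: pair (i, j) true iff an edge exists either way."""
        a = self.directed_adjacency != 0
        return a | a.T

    @property
    def n_true_connections(self) -> int:
        """Number of unordered node pairs linked in at least one direction."""
        u = self.undirected_pairs
        return int(np.triu(u, k=1).sum())


@dataclass
class AssociationMatrix:
    """Symmetric, non-negative, zero-diagonal matrix of connection strengths."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("association matrix must be exactly symmetric")
        if np.any(a < 0):
            raise ValueError("association matrix must be non-negative")
        if np.any(np.diag(a) != 0):
            raise ValueError("association matrix diagonal must be zero")
        if not self.node_ids:
            self.node_ids = [f"n{i + 1}" for i in range(a.shape[0])]
        if len(self.node_ids) != a.shape[0]:
            raise ValueError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def global_mean(self) -> float:
        """Average over all entries, diagonal included."""
        return float(self.values.mean())


@dataclass
class CoefficientVector:
    """Sparse-representation coefficients for one node.

    ``w`` has length n-1 (the node's dictionary excludes itself); ``padded``
    is w with a zero inserted at the node's own position, length n.
    """

    w: np.ndarray
    padded: np.ndarray
    node_index: int
    objective: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.padded = np.asarray(self.padded, dtype=float)
        if self.padded.shape[0] != self.w.shape[0] + 1:
            raise ValueError("padded vector must have one extra entry")
        if self.padded[self.node_index] != 0.0:
            raise ValueError("padded vector must be exactly zero at its own node")
        recovered = np.delete(self.padded, self.node_index)
        if not np.array_equal(recovered, self.w):
            raise ValueError("padded vector inconsistent with w")


@dataclass
class CoefficientMatrix:
    """Stacked padded coefficient vectors, one column per node."""

    values: np.ndarray
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diag(self.values) != 0):
            raise ValueError("coefficient matrix diagonal must be exactly zero")


@dataclass
class ClusterAssignment:
    """Affinity-propagation result: labels, exemplars and diagnostics."""

    labels: np.ndarray
    exemplars: np.ndarray
    converged: bool
    net_similarity: float
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.exemplars = np.asarray(self.exemplars, dtype=int)
        for e in self.exemplars:
            if self.labels[e] != self.labels[e]:  # pragma: no cover - sanity
                raise ValueError("exemplar label inconsistent")

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    @property
    def K(self) -> int:
        return self.n_clusters
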