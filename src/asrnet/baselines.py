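"""Correlation-based association matrices used as comparison baselines.

The Pearson matrix scores each pair of nodes in isolation; the partial
correlation conditions each pair on every other node via the precision
matrix. Both are returned with absolute values so they share the
non-negative similarity semantics of the sparse-representation estimator;
a ``signed`` flag exposes the raw coefficients as a plain array when the
sign matters.
"""

from __future__ import annotations

import numpy as np

from .containers import AssociationMatrix, TimeSeriesMatrix

__all__ = ["pearson_association", "partial_correlation_association"]


def _values(X: TimeSeriesMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, TimeSeriesMatrix):
        return X.values, list(X.node_ids)
    arr = np.asarray(X, dtype=float)
    return arr, []


def pearson_association(
    X: TimeSeriesMatrix | np.ndarray, signed: bool = False
) -> AssociationMatrix:
    """Pairwise Pearson correlation matrix, |r| off-diagonal, zero diagonal."""
    values, node_ids = _values(X)
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        ids = node_ids or [f"n{i + 1}" for i in range(values.shape[1])]
        raise ValueError(f"constant column for node {ids[bad]!r}")
    r = np.corrcoef(values, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    if signed:
        return r  # signed coefficients cannot form a (non-negative) AssociationMatrix
    return AssociationMatrix(np.abs(r), node_ids=node_ids)


def partial_correlation_association(
    X: TimeSeriesMatrix | np.ndarray, signed: bool = False, ridge: bool = True
) -> AssociationMatrix:
    """Partial correlations from the inverse sample covariance.

    With precision matrix P, the partial correlation of nodes i and j
    given all others is -p_ij / sqrt(p_ii p_jj). When the covariance is
    singular (or nearly so) a small ridge ``1e-8 * trace/n * I`` is added
    before inversion; set ``ridge=False`` to fail instead.

    For n = 2 there is nothing to condition on and the result equals the
    Pearson matrix.
    """
    values, node_ids = _values(X)
    n = values.shape[1]
    cov = np.cov(values, rowvar=False)
    if ridge:
        cov = cov + (1e-8 * np.trace(cov) / n) * np.eye(n)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance; enable ridge or add data") from exc
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 0.0)
    if signed:
        return pc
    return AssociationMatrix(np.abs(pc), node_ids=node_ids)
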