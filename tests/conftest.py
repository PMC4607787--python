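"""Shared fixtures and independent oracle implementations.

The oracles here deliberately take different computational routes from the
package (smooth optimization instead of ADM, exhaustive enumeration
instead of message passing / Louvain, hand ANOVA instead of the packaged
formulas) so that agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from asrnet import RingNetworkSpec, normalize_node_series, simulate_ring_network


def random_unit_columns(rng: np.random.Generator, d: int, m: int) -> np.ndarray:
    X = rng.normal(size=(d, m))
    return X / np.linalg.norm(X, axis=0)


def trace_lasso_objective(y, X, w, lam) -> float:
    r = y - X @ w
    nuc = np.linalg.svd(X * w, compute_uv=False).sum()
    return 0.5 * float(r @ r) + lam * float(nuc)


def smooth_oracle_solve(y: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    """Independent minimizer of the trace-LASSO regression objective.

    Replaces the nuclear norm by a Huber-smoothed sum of singular values
    and runs L-BFGS-B with smoothing continuation down to 1e-8. For the
    tiny problems used in tests this attains the optimum to ~1e-8.
    """

    def fg(w, ms):
        U, s, Vt = np.linalg.svd(X * w, full_matrices=False)
        h = np.where(s > ms, s - ms / 2, s**2 / (2 * ms))
        hp = np.where(s > ms, 1.0, s / ms)
        r = X @ w - y
        f = 0.5 * r @ r + lam * h.sum()
        g = X.T @ r + lam * np.einsum("ij,ij->j", X, (U * hp) @ Vt)
        return f, g

    w = np.zeros(X.shape[1])
    for ms in (1e-2, 1e-4, 1e-6, 1e-8):
        w = minimize(
            fg,
            w,
            args=(ms,),
            jac=True,
            method="L-BFGS-B",
            options=dict(maxiter=2000, ftol=1e-16, gtol=1e-12),
        ).x
    return w


def brute_force_net_similarity(S: np.ndarray, preference: float) -> float:
    """Best achievable affinity-propagation objective by enumerating
    every non-empty exemplar subset."""
    n = S.shape[0]
    best = -np.inf
    nodes = range(n)
    for r in range(1, n + 1):
        for subset in itertools.combinations(nodes, r):
            ex = np.array(subset)
            members = np.setdiff1d(np.arange(n), ex)
            val = len(ex) * preference
            if members.size:
                val += S[np.ix_(members, ex)].max(axis=1).sum()
            if val > best:
                best = val
    return float(best)


def brute_force_modularity(A: np.ndarray, gamma: float = 1.0) -> float:
    """Maximum weighted modularity over every partition (Bell-number
    enumeration; use only for n <= 10)."""
    n = A.shape[0]
    two_m = A.sum()
    degrees = A.sum(axis=1)

    def q_of(assign):
        q = 0.0
        for c in set(assign):
            idx = [i for i, a in enumerate(assign) if a == c]
            e_c = A[np.ix_(idx, idx)].sum() / two_m
            d_c = degrees[idx].sum() / two_m
            q += e_c - gamma * d_c**2
        return q

    best = -np.inf
    for assign in _set_partitions(n):
        best = max(best, q_of(assign))
    return float(best)


def _set_partitions(n: int):
    """Yield all set partitions of range(n) in restricted-growth form."""

    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield tuple(prefix)
            return
        for c in range(k + 1):
            yield from rec(prefix + [c], max(k, c + 1))

    yield from rec([], 0)


def brute_force_accuracy(labels, true_labels) -> float:
    """Best agreement over every injective mapping of predicted cluster
    ids onto true cluster ids (exhaustive, small label sets only)."""
    labels = np.asarray(labels)
    true_labels = np.asarray(true_labels)
    pred = np.unique(labels)
    true = np.unique(true_labels)
    best = 0
    # pad the smaller side so the mapping is a bijection on the larger set
    if len(pred) <= len(true):
        for perm in itertools.permutations(true, len(pred)):
            mapping = dict(zip(pred, perm))
            best = max(best, sum(mapping[p] == t for p, t in zip(labels, true_labels)))
    else:
        for perm in itertools.permutations(pred, len(true)):
            mapping = dict(zip(perm, true))
            best = max(
                best,
                sum(mapping.get(p) == t for p, t in zip(labels, true_labels)),
            )
    return best / labels.size


@pytest.fixture(scope="session")
def small_ring_spec() -> RingNetworkSpec:
    """A 3-ring, 4-node-per-ring network: fast but structurally faithful."""
    return RingNetworkSpec(n_rings=3, ring_size=4, n_timepoints=120, inter_links=3, seed=7)


@pytest.fixture(scope="session")
def small_subject(small_ring_spec):
    ts, truth = simulate_ring_network(small_ring_spec)
    return normalize_node_series(ts), truth
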