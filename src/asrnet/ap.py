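"""Affinity propagation clustering on association matrices.

Exemplar-based clustering by responsibility/availability message passing.
The association matrix is used directly as the similarity matrix, with a
common preference value on the diagonal controlling how many clusters
emerge; larger preferences yield more clusters. Updates are damped and,
unlike most implementations, no random tie-breaking jitter is added by
default, so results are fully deterministic; a seeded jitter can be
switched on for degenerate inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .containers import AssociationMatrix, ClusterAssignment

__all__ = ["APConfig", "affinity_propagation", "preference_for_k", "net_similarity"]


@dataclass(frozen=True)
class APConfig:
    """Affinity propagation settings.

    ``preference`` is the shared self-similarity for all nodes (``None``
    means the median off-diagonal similarity). ``convits`` is the number
    of consecutive iterations the exemplar set must stay unchanged to
    declare convergence. ``jitter_seed`` enables a tiny (1e-12-scale)
    seeded perturbation of the similarities for degenerate inputs.
    """

    preference: float | None = None
    damping: float = 0.9
    max_iter: int = 1000
    convits: int = 100
    jitter_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1:
            raise ValueError("damping must lie in [0.5, 1)")
        if self.max_iter < 1 or self.convits < 1:
            raise ValueError("max_iter and convits must be positive")


def _similarity(S: AssociationMatrix | np.ndarray) -> np.ndarray:
    if isinstance(S, AssociationMatrix):
        return np.array(S.values, dtype=float)
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    return S.copy()


def net_similarity(S: np.ndarray, preference: float, exemplars: np.ndarray) -> float:
    """Objective AP maximises: each point's similarity to its exemplar,
    plus the preference of every exemplar."""
    exemplars = np.asarray(exemplars, dtype=int)
    n = S.shape[0]
    members = np.setdiff1d(np.arange(n), exemplars)
    total = float(len(exemplars)) * preference
    if members.size:
        total += float(S[np.ix_(members, exemplars)].max(axis=1).sum())
    return total


def affinity_propagation(
    S: AssociationMatrix | np.ndarray, config: APConfig | None = None
) -> ClusterAssignment:
    """Cluster by responsibility/availability message passing.

    The diagonal of the similarity matrix is replaced by the preference.
    Convergence means the exemplar set was stable for ``convits``
    iterations; otherwise the last assignment is returned with
    ``converged=False``. Ties in the final assignment go to the
    lowest-index exemplar.
    """
    config = config or APConfig()
    sim = _similarity(S)
    n = sim.shape[0]
    pref = (
        float(np.median(sim[~np.eye(n, dtype=bool)]))
        if config.preference is None
        else float(config.preference)
    )
    np.fill_diagonal(sim, pref)
    if config.jitter_seed is not None:
        rng = np.random.default_rng(config.jitter_seed)
        scale = 1e-12 * max(np.ptp(sim), 1.0)
        sim = sim + scale * rng.standard_normal(sim.shape)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    damp = config.damping
    idx = np.arange(n)

    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        # responsibilities
        AS = A + sim
        first = AS.max(axis=1)
        first_k = AS.argmax(axis=1)
        AS_wo = AS.copy()
        AS_wo[idx, first_k] = -np.inf
        second = AS_wo.max(axis=1)
        R_new = sim - first[:, None]
        R_new[idx, first_k] = sim[idx, first_k] - second
        R = damp * R + (1 - damp) * R_new

        # availabilities
        Rp = np.maximum(R, 0.0)
        Rp[idx, idx] = R[idx, idx]
        col = Rp.sum(axis=0)
        A_new = np.minimum(0.0, col[None, :] - Rp)
        A_new[idx, idx] = col - R[idx, idx]
        A = damp * A + (1 - damp) * A_new

        exemplars = np.flatnonzero(np.diag(R) + np.diag(A) > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
        else:
            stable = 0
        prev_exemplars = exemplars
        if stable >= config.convits and exemplars.size > 0:
            converged = True
            break

    if prev_exemplars is None or prev_exemplars.size == 0:
        # degenerate: fall back to the single best self-evidence exemplar
        best = int(np.argmax(np.diag(R) + np.diag(A)))
        prev_exemplars = np.array([best])
        converged = False
    exemplars = prev_exemplars
    labels = np.asarray(sim[:, exemplars].argmax(axis=1), dtype=int)
    labels[exemplars] = np.arange(len(exemplars))
    return ClusterAssignment(
        labels=labels,
        exemplars=exemplars,
        converged=converged,
        net_similarity=net_similarity(_similarity(S), pref, exemplars),
        n_iter=n_iter,
    )


def preference_for_k(
    S: AssociationMatrix | np.ndarray,
    K_target: int,
    tolerance: int = 1,
    config: APConfig | None = None,
) -> tuple[float, ClusterAssignment]:
    """Bisection search on the preference for a requested cluster count.

    The cluster count is non-decreasing in the preference in practice, so
    a bisection between the smallest and largest off-diagonal similarity
    (with bracket expansion when needed) homes in on ``K_target``. The
    closest K seen is kept; if no preference within the bracket achieves
    ``|K - K_target| <= tolerance`` the best found is returned with a
    warning.
    """
    config = config or APConfig()
    sim = _similarity(S)
    n = sim.shape[0]
    if not 1 <= K_target <= n:
        raise ValueError("K_target must lie in [1, n]")
    off = sim[~np.eye(n, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())
    if hi <= lo:
        hi = lo + 1.0

    def run(p: float) -> ClusterAssignment:
        return affinity_propagation(S, replace(config, preference=p))

    best: tuple[int, float, ClusterAssignment] | None = None

    def consider(p: float, asg: ClusterAssignment) -> None:
        nonlocal best
        gap = abs(asg.n_clusters - K_target)
        if best is None or gap < best[0]:
            best = (gap, p, asg)

    span = hi - lo
    asg_lo = run(lo)
    consider(lo, asg_lo)
    for _ in range(10):
        if asg_lo.n_clusters <= K_target:
            break
        lo -= span
        span *= 2
        asg_lo = run(lo)
        consider(lo, asg_lo)
    asg_hi = run(hi)
    consider(hi, asg_hi)
    for _ in range(10):
        if asg_hi.n_clusters >= K_target:
            break
        hi += span
        span *= 2
        asg_hi = run(hi)
        consider(hi, asg_hi)

    for _ in range(60):
        if best is not None and best[0] <= tolerance:
            break
        mid = (lo + hi) / 2.0
        asg = run(mid)
        consider(mid, asg)
        if asg.n_clusters < K_target:
            lo = mid
        else:
            hi = mid

    assert best is not None
    gap, pref, asg = best
    if gap > tolerance:
        warnings.warn(
            f"preference search reached K={asg.n_clusters} "
            f"(target {K_target}, tolerance {tolerance})",
            RuntimeWarning,
        )
    return pref, asg
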