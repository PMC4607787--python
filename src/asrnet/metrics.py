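"""Evaluation metrics for estimated networks and their clusterings.

Covers connection sensitivity against a directed ground truth,
Hungarian-matched clustering accuracy, a similarity-based Silhouette index
(with a global-mean alignment step for cross-estimator comparability),
weighted Newman modularity with Louvain community detection, and the
two-way mixed-model single-measure consistency ICC for test-retest
reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import AssociationMatrix, GroundTruthNetwork

__all__ = [
    "sensitivity",
    "clustering_accuracy",
    "silhouette_similarity",
    "align_global_mean",
    "modularity_communities",
    "icc_c1",
    "MetricsReport",
]


def _matrix(A: AssociationMatrix | np.ndarray) -> np.ndarray:
    if isinstance(A, AssociationMatrix):
        return A.values
    return np.asarray(A, dtype=float)


def sensitivity(
    A: AssociationMatrix | np.ndarray,
    truth: GroundTruthNetwork,
    tie_strict: bool = True,
    percentile_method: str = "linear",
) -> float:
    """Fraction of true-connection strengths above the 95th percentile of
    false-connection strengths (c-sensitivity).

    The ground truth is directed while the association matrix is not, so
    an unordered pair counts as truly connected when an edge exists in
    either direction. True-positive strengths are the association values
    over the true pairs, false-positive strengths those over all other
    pairs; the score is #{TP > q95(FP)} / #{TC}.

    ``percentile_method`` is ``"linear"`` (interpolated, default) or
    ``"nearest"`` (nearest-rank). ``tie_strict=False`` counts ties at the
    threshold as detected.
    """
    a = _matrix(A)
    n = a.shape[0]
    if truth.n_nodes != n:
        raise ValueError("association matrix and ground truth sizes differ")
    iu = np.triu_indices(n, k=1)
    true_pair = truth.undirected_pairs[iu]
    tp = a[iu][true_pair]
    fp = a[iu][~true_pair]
    if tp.size == 0:
        raise ValueError("ground truth has no true connections")
    if fp.size == 0:
        raise ValueError("ground truth has no false (unconnected) pairs")
    method = {"linear": "linear", "nearest": "inverted_cdf"}[percentile_method]
    q95 = np.percentile(fp, 95, method=method)
    hits = tp > q95 if tie_strict else tp >= q95
    return float(hits.sum() / tp.size)


def clustering_accuracy(labels, true_labels) -> float:
    """Share of nodes correctly labelled after optimally matching
    predicted clusters to true clusters (Hungarian assignment).

    The agreement matrix may be rectangular; unmatched predicted clusters
    contribute nothing. Invariant under any renaming of predicted labels.
    """
    labels = np.asarray(labels)
    true_labels = np.asarray(true_labels)
    if labels.shape != true_labels.shape:
        raise ValueError("label vectors must have equal length")
    if labels.size == 0:
        raise ValueError("empty labelings")
    pred_ids, pred_inv = np.unique(labels, return_inverse=True)
    true_ids, true_inv = np.unique(true_labels, return_inverse=True)
    agreement = np.zeros((len(pred_ids), len(true_ids)), dtype=int)
    np.add.at(agreement, (pred_inv, true_inv), 1)
    rows, cols = linear_sum_assignment(agreement, maximize=True)
    return float(agreement[rows, cols].sum() / labels.size)


def silhouette_similarity(
    A: AssociationMatrix | np.ndarray, labels
) -> tuple[np.ndarray, float]:
    """Per-node and mean Silhouette computed from similarities.

    a(i) is the mean similarity of node i to the other members of its own
    cluster, b(i) the largest mean similarity to any other cluster, and
    s(i) = (a - b) / max(a, b). Nodes in singleton clusters score 0.
    Invariant under rescaling of the similarities (but not translation:
    compare matrices only after :func:`align_global_mean`).
    """
    a = _matrix(A)
    labels = np.asarray(labels)
    n = a.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match matrix size")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("Silhouette needs at least two clusters")
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own) & (np.arange(n) != i)
        if not mask_own.any():
            s[i] = 0.0  # singleton cluster
            continue
        ai = a[i, mask_own].mean()
        bi = max(a[i, labels == c].mean() for c in clusters if c != own)
        denom = max(ai, bi)
        s[i] = 0.0 if denom == 0 else (ai - bi) / denom
    return s, float(s.mean())


def align_global_mean(
    A_list: list[AssociationMatrix | np.ndarray],
) -> list[np.ndarray]:
    """Translate matrices so they share the same global mean.

    The global mean is the average over all entries, diagonal included.
    The common target is the mean of the input means; each matrix's
    off-diagonal entries are shifted by ``(target - own) * n^2 / (n^2 - n)``
    so the diagonal stays zero while the full-matrix mean reaches the
    target. Translated copies can carry negative entries, so plain arrays
    are returned.
    """
    if len(A_list) < 2:
        raise ValueError("need at least two matrices to align")
    mats = [_matrix(A).copy() for A in A_list]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all matrices must have the same size")
    means = [m.mean() for m in mats]
    target = float(np.mean(means))
    out = []
    off_mask = ~np.eye(n, dtype=bool)
    for m, mean in zip(mats, means):
        shift = (target - mean) * n * n / (n * n - n)
        m2 = m.copy()
        m2[off_mask] += shift
        out.append(m2)
    return out


def modularity_communities(
    A: AssociationMatrix | np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[float, np.ndarray, int]:
    """Weighted Newman modularity of the best Louvain partition.

    Q = sum_c (e_c / m - (d_c / 2m)^2) over communities, maximized by
    Louvain with ``n_restarts`` seeded restarts (seeds ``seed`` ..
    ``seed + n_restarts - 1``); the partition with the highest Q wins.
    Returns (Q, community labels, number of communities).
    """
    a = _matrix(A)
    if a.sum() <= 0:
        raise ValueError("graph has zero total weight")
    G = nx.from_numpy_array(a)
    best_q = -np.inf
    best_parts: list[set] | None = None
    for s in range(seed, seed + n_restarts):
        parts = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=int(s) % (2**31)
        )
        q = nx.community.modularity(G, parts, weight="weight", resolution=gamma)
        if q > best_q:
            best_q = q
            best_parts = parts
    assert best_parts is not None
    labels = np.zeros(a.shape[0], dtype=int)
    for c, members in enumerate(best_parts):
        for node in members:
            labels[node] = c
    return float(best_q), labels, len(best_parts)


def icc_c1(data: np.ndarray) -> float:
    """Two-way mixed-model single-measure consistency ICC.

    ``data`` is subjects x sessions with no missing cells. With MS_B the
    between-subjects mean square and MS_E the residual mean square of the
    two-way (subject + session) decomposition,

        ICC(C,1) = (MS_B - MS_E) / (MS_B + (k - 1) * MS_E)

    for k sessions. Consistency, not absolute agreement: adding a
    per-session constant leaves the value unchanged.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a subjects x sessions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    sess_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_sess = n * float(((sess_means - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_sess
    ms_b = ss_subj / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_b + (k - 1) * ms_e
    if denom == 0:
        raise ValueError("zero variance in every direction; ICC undefined")
    return float((ms_b - ms_e) / denom)


@dataclass
class MetricsReport:
    """Bundle of per-subject evaluation results.

    Only the metrics that were actually computed are populated; ``details``
    carries auxiliary quantities (per-node Silhouette values, community
    labels, counts) keyed by metric name.
    """

    sensitivity: float | None = None
    accuracy: float | None = None
    silhouette_mean: float | None = None
    modularity_Q: float | None = None
    n_communities: int | None = None
    icc: float | None = None
    details: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {}
        for key in (
            "sensitivity",
            "accuracy",
            "silhouette_mean",
            "modularity_Q",
            "n_communities",
            "icc",
        ):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out
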