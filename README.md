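# asrnet

Whole-network functional connectivity estimation for resting-state fMRI
by **adaptive sparse representation** (trace-LASSO-regularized regression),
with **affinity propagation** clustering to identify sub-networks, and a
full evaluation toolkit (connection sensitivity, Hungarian-matched
clustering accuracy, similarity Silhouette, weighted modularity,
test-retest ICC). A built-in simulator of ring-cluster network time series
makes every stage testable without any external data.

## Who this is for

Researchers estimating functional brain networks from node time series
(ROI-averaged fMRI or simulated data) who want a *multivariate* and
*adaptive* alternative to pairwise Pearson correlation: each node is
regressed on all other nodes at once, with a penalty that adapts to how
correlated the regressors are.

## The model

Given a data matrix X = [x_1, …, x_n] ∈ R^{d×n} (d time points, n nodes,
every column demeaned and scaled to unit ℓ2 norm), the association of node
i with the rest of the network is the solution of

    min_w  (1/2) ‖x_i − X_i w‖²  +  λ ‖X_i Diag(w)‖_*

where X_i is X without column i and ‖·‖_* is the nuclear (trace) norm. The
trace-LASSO penalty ‖X Diag(w)‖_* interpolates between the two classical
extremes,

    ‖w‖₂  ≤  ‖X Diag(w)‖_*  ≤  ‖w‖₁ ,

equalling the ℓ1 norm when the dictionary columns are orthogonal (sparse,
lasso-like selection) and the ℓ2 norm when they are identical (stable,
ridge-like grouping) — so it selects single uncorrelated predictors yet
keeps groups of correlated nodes together. λ has a closed-form upper bound
‖X_i‖_op · ‖X_iᵀ x_i‖_∞ above which w = 0.

The problem is solved by an alternating direction method: an auxiliary
variable carries the nuclear norm (its update is singular-value
soft-thresholding), the coefficient update is a small linear solve, and
an augmented-Lagrangian multiplier with a growing penalty enforces the
split. The coefficient vectors are padded with a zero at each node's own
position, stacked into W, and symmetrized into the association matrix
A = (|W| + |Wᵀ|)/2 — symmetric, non-negative, zero diagonal.

Sub-networks are then identified by affinity propagation directly on A
(no thresholding): exemplar-based message passing whose single
"preference" parameter controls the number of clusters; a bisection
search finds the preference yielding a requested cluster count.

## Worked example

```python
import numpy as np
from asrnet import (
    RingNetworkSpec, simulate_ring_network, normalize_node_series,
    SolverConfig, asr_association_matrix, pearson_association,
    preference_for_k, sensitivity, clustering_accuracy,
    modularity_communities,
)

# 3 linked 5-node rings, 200 time points, noise on neural and signal level
spec = RingNetworkSpec(n_rings=3, ring_size=5, n_timepoints=200,
                       inter_links=3, seed=42)
ts, truth = simulate_ring_network(spec)
X = normalize_node_series(ts)

A, W = asr_association_matrix(X, SolverConfig(lam=0.2))
print("sensitivity:", round(sensitivity(A, truth), 3))

pref, asg = preference_for_k(A, K_target=3)
print("clusters:", asg.n_clusters,
      "accuracy:", round(clustering_accuracy(asg.labels, truth.true_labels), 3))

q, _, n_comm = modularity_communities(A, seed=0)
print("modularity: %.3f over %d communities" % (q, n_comm))

iu = np.triu_indices(15, 1)
print("near-zero fraction ASR: %.2f  Pearson: %.2f" % (
    (A.values[iu] < 1e-6).mean(),
    (pearson_association(X).values[iu] < 1e-6).mean()))
```

prints

```
sensitivity: 0.722
clusters: 3 accuracy: 0.933
modularity: 0.555 over 3 communities
near-zero fraction ASR: 0.70  Pearson: 0.00
```

Reading: 72% of the true connections score above the 95th percentile of
the false-connection strengths; affinity propagation recovers the three
rings with 93% node accuracy; and the sparse-representation matrix drives
70% of all pairwise strengths to (numerically) zero where the dense
correlation matrix has none — the sparsity that makes the network's
community structure stand out (modularity 0.56).

The same workflow is available from the shell:

```sh
asrnet simulate --n-subjects 10 --out data/
asrnet pipeline --estimator asr --estimator pearson --k-target 10 \
       --seed 0 --out runs/demo/
```

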