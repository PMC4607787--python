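# Methods

This note documents the models, algorithms and numerical choices behind
`asrnet`, and what its synthetic benchmark does and does not establish.

## Association estimation by adaptive sparse representation

Each node's (demeaned, unit-norm) series y is regressed on the dictionary
X of all other nodes under the trace-LASSO penalty λ‖X Diag(w)‖_* (the
nuclear norm of the column-scaled dictionary). Because
‖w‖₂ ≤ ‖X Diag(w)‖_* ≤ ‖w‖₁, with the ℓ2 extreme attained for identical
columns and the ℓ1 extreme for orthogonal ones, the penalty adapts its
geometry to the local correlation structure: uncorrelated nodes are
selected sparsely, correlated groups enter or leave together. The
per-node coefficient vectors, zero-padded at the node's own position,
form the columns of W; the reported association matrix is
A = (|W| + |W|ᵀ)/2, which is symmetric, elementwise non-negative and
zero on the diagonal by construction. The absolute value is applied to
the padded matrix; the padding zeros are unaffected.

### ADM solver

The penalized objective (1/2)‖y − Xw‖² + λ‖X Diag(w)‖_* is minimized by
an alternating direction method with the splitting J = X Diag(w):

1. **w-update** — closed form: (XᵀX + μI) w = Xᵀy + μ·diag(Xᵀ(J − Y/μ)),
   solved through a one-time eigendecomposition of XᵀX;
2. **J-update** — singular-value soft-thresholding at level λ/μ (the
   proximal operator of the nuclear norm);
3. **multiplier** — Y ← Y + μ(X Diag(w) − J), then μ ← min(ρμ, μ_max).

All iterations run in the reduced space of an economic QR of the
dictionary (X = QR): the nuclear norm and the residual decompose exactly,
so the per-iteration SVD is m×m (m = n−1 nodes) instead of d×m, which
matters when time series are long.

Defaults: μ₀ = 1e−2, ρ = 1.1, μ_max = 1e6, tol = 1e−6, max_iter = 500.
The stopping rule requires both the primal residual ‖X Diag(w) − J‖_F and
a dual residual below tol. The dual residual is measured as the
*relative change* ‖J_k − J_{k−1}‖_F / max(1, ‖J_k‖_F): the textbook
μ-scaled dual residual μ‖Aᵀ(J_k − J_{k−1})‖ becomes meaningless once μ
reaches its cap, where it amplifies machine-precision fluctuations of an
already-stationary iterate above any reasonable tolerance. On small
problems the ADM solution agrees with an independent smooth-optimization
oracle to ~1e−8 relative in objective (see below). Non-convergence
within max_iter returns the last iterate flagged `converged=False`; the
association assembly records per-node diagnostics (iterations,
objective, residual, convergence).

The constrained formulation's feasibility parameter ε is reported post
hoc as the achieved residual; it is never enforced.

### λ and its selection

`lambda_upper_bound` returns ‖X‖_op·‖Xᵀy‖_∞, the smallest λ with w = 0;
on normalized network data the per-node bounds sit near 1.
`lambda_grid(lam_max)` descends four decades from the bound and then
sweeps 0.30…0.10 in steps of 0.01; `select_lambda` evaluates the full
association matrix over the grid and maximizes either connection
sensitivity (needs ground truth) or modularity (unsupervised), using
only fully converged fits and breaking ties toward the larger (sparser)
λ. A fixed-λ policy bypasses the search; λ = 0.2 is the package-wide
default operating point. Sparsity reporting counts entries below 1e−6 as
"near zero" (solver output is never exactly zero).

### Independent solver oracle

The test suite verifies ADM optimality against a genuinely different
algorithm: the nuclear norm is replaced by a Huber-smoothed sum of
singular values (a differentiable spectral function), minimized by
L-BFGS-B with smoothing continuation 1e−2 → 1e−8. On problems with
d ≤ 15, n ≤ 8 this attains the optimum to ~1e−8 and the ADM objective
matches it within 1e−5 relative.

## Baselines

Pearson association |r_ij| and partial correlation |−p_ij/√(p_ii p_jj)|
from the inverse sample covariance (with an optional ridge
1e−8·trace/n·I for near-singular covariances). Absolute values give all
estimators the same non-negative similarity semantics; signed variants
return plain arrays since a signed matrix is not a valid association
matrix.

## Affinity propagation

Standard responsibility/availability message passing with damping
(default 0.9 — near-block-constant association matrices need heavy
damping), max_iter 1000, and convergence declared after 100 iterations
of an unchanged exemplar set. Unlike most implementations no random
jitter is added, so results are exactly reproducible; a seeded jitter
flag exists for degenerate (exactly tied) inputs. Final assignments
break ties toward the lowest-index exemplar. The preference (shared by
all nodes) defaults to the median off-diagonal similarity.
`preference_for_k` bisects the preference between the smallest and
largest off-diagonal similarity (expanding the bracket when needed,
≤ 60 bisection steps), keeps the closest cluster count seen, and warns
if the target is missed by more than the tolerance — cluster count is
non-decreasing in the preference in practice but not guaranteed to be.

On random 8×8 similarity matrices the converged message-passing solution
attains the exhaustively enumerated exemplar-set optimum in well over
80% of cases and never exceeds it.

## Evaluation metrics

- **Connection sensitivity**: the ground truth is directed, the
  estimate undirected, so an unordered pair is "true" when an edge
  exists in either direction and the true-connection count #TC is
  pair-level. The score is #{TP > q95(FP)}/#TC with a strict inequality;
  q95 uses linearly interpolated percentiles by default (nearest-rank is
  available).
- **Clustering accuracy**: maximum-agreement matching of predicted to
  true clusters via the Hungarian algorithm on the (possibly
  rectangular) contingency table; unmatched clusters contribute zero.
- **Silhouette on similarities**: a(i) is the mean within-cluster
  similarity, b(i) the best other-cluster mean, s(i) = (a−b)/max(a,b);
  singleton clusters score 0. The index is scale-invariant but not
  translation-invariant, so cross-estimator comparisons first translate
  all matrices to a common global mean (off-diagonal shift by
  (target − own)·n²/(n²−n), keeping diagonals at zero).
- **Modularity**: weighted Newman modularity maximized by Louvain with
  10 seeded restarts (best of), resolution γ = 1, matrices passed
  unthresholded. Exhaustive partition enumeration confirms optimality on
  small graphs.
- **ICC(C,1)**: two-way (subject × session) decomposition,
  (MS_B − MS_E)/(MS_B + (k−1)MS_E) — consistency, so per-session
  constant shifts cancel.

## The synthetic cohort

`RingNetworkSpec` emulates a standard simulated resting-state benchmark:
50 subjects, 50 nodes, 200 time points at TR = 3 s, ground truth of ten
linked five-node directed rings, noise at both the neural and the
observed-signal level. The original benchmark was generated by dynamic
causal modelling; this package substitutes a stable first-order vector
autoregression, because only the topology and the noise structure — not
the biophysics — are needed to exercise the estimators.

Default parameters (chosen once, as a package design decision, to place
the baseline estimators in the benchmark's qualitative regime —
separable clusters, sensitivities in the high-0.8 range, neither ceiling
nor floor):

| parameter | default | meaning |
|---|---|---|
| `self_coupling` | 0.6 | AR(1) carry-over of each node on itself |
| `intra_coupling` | 0.35 | directed ring link j → j+1 |
| `inter_links` | 8 | random weak directed links between rings |
| `inter_coupling` | intra/3 | strength of those links |
| `ring_drive_corr` | 0.3 | correlation of innovations within a ring |
| `neural_noise_sd` | 1.0 | VAR innovation scale |
| `signal_noise_sd` | 0.9 | additive observation noise |
| `hrf_smoothing` | off | double-gamma convolution (peak 6 s, undershoot 16 s, unit peak, sampled at TR) |

Two of these deserve explanation because a naive lag-only ring VAR fails
qualitatively:

- **`self_coupling`** — with purely lagged coupling and no
  autoregressive memory, ring neighbours are *exactly uncorrelated at
  lag zero*, so no undirected estimator could see the rings at all. The
  self term is the discrete-time analogue of the signal sluggishness
  that, in real BOLD data, folds lagged neural influence into
  instantaneous correlation.
- **`ring_drive_corr`** — in a pure chain, nodes two steps apart on a
  ring are conditionally (and nearly marginally) independent, so rings
  cannot behave as *clusters* for any clustering algorithm. The
  benchmark's clusters co-activate as wholes; a shared ring-level
  innovation component reproduces that, and is the standard way to give
  a functional module a common drive.

The simulator asserts the spectral radius of the transition matrix is
below 1 and reports it when violated. One integer seed determines
everything; per-subject series seeds derive from a base seed while the
topology (including the random inter-ring links) depends only on the
spec's own seed, so a cohort shares one ground truth.

**What the synthetic benchmark does not show.** The generator has linear
Gaussian dynamics, identical topology and parameters across subjects,
no haemodynamic nonlinearity, no physiological confounds, no
subject-level topology variation and no spatial structure. Passing tests
demonstrate correctness of the estimators and the orderings *within this
regime*; they do not establish effect sizes on real fMRI. The
`read_netsim_mat` reader accepts the original external benchmark bundle
(MAT v5) for users who have downloaded it.

## Pipeline determinism and problem sizes

The pipeline is a pure function of (config, seed): simulation seeds,
solver state, clustering and Louvain restarts are all derived from the
configuration, and text artifacts are written with fixed float formats,
so reruns are byte-identical. The bundled experiment script runs the
full 50-subject cohort at the default 50-node size; the test suite
exercises the same paths at 12–15 nodes and 10 subjects, sizes chosen to
keep the whole suite in a few minutes while leaving every algorithmic
branch covered. The test-retest demonstration gives subjects a
subject-specific intra-ring coupling (SD 0.01 around 0.35) so that the
between-subject variance of the global mean is a stable trait and
ICC(C,1) lands in the moderate-to-good band typical of connectivity
metrics rather than saturating at 1.

## Known limitations

- The ADM penalty schedule (geometric μ growth) trades dual accuracy for
  speed; objectives are accurate to ~1e−6 relative, which is far below
  metric resolution but not certificate-grade optimality.
- Affinity propagation assigns each node to exactly one cluster;
  overlapping sub-networks are out of scope.
- `select_lambda` with the sensitivity criterion uses the ground truth
  and is therefore only meaningful on simulated data; the modularity
  criterion is the unsupervised alternative.
- Partial correlation requires d comfortably above n or the ridge
  stabilizer; no graphical-lasso-style regularized precision estimation
  is provided.
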