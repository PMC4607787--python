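"""Synthetic resting-state fMRI generator with known network structure.

The flagship generator emulates the netsim "Sim4" regime: 50 subjects,
50 nodes, 200 time points at TR = 3 s, where the underlying network is 10
linked clusters, each a five-node directed ring, and noise enters at both
the neural and the observed (mean signal) level. The original benchmark
was produced by dynamic causal modelling; here a stable first-order vector
autoregression with optional haemodynamic smoothing stands in — only the
topology and the noise structure are emulated, not the biophysics.

A second generator produces groups of mutually correlated Gaussian series
(a single-factor model per group), the canonical fixture for checking the
grouping effect of trace-LASSO regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .containers import GroundTruthNetwork, TimeSeriesMatrix

__all__ = [
    "RingNetworkSpec",
    "simulate_ring_network",
    "simulate_correlated_groups",
    "simulate_multisubject",
    "hrf_kernel",
]


@dataclass(frozen=True)
class RingNetworkSpec:
    """Parameters of the ring-cluster VAR(1) simulator.

    Attributes
    ----------
    n_rings, ring_size
        Cluster layout; total node count is ``n_rings * ring_size``.
    n_timepoints
        Length of each subject's series (default 200).
    tr_seconds
        Sampling interval, used only to sample the haemodynamic kernel
        (default 3 s).
    self_coupling
        Autoregressive carry-over of each node on itself. This models the
        sluggishness of the observed signal; without it, purely lagged ring
        coupling would leave neighbouring nodes uncorrelated at lag zero.
    intra_coupling
        Strength of the directed link j -> j+1 (mod ring size) within a ring.
    inter_links
        Number of random weak directed links between distinct rings; the
        rings are "linked" but remain separable clusters.
    inter_coupling
        Strength of the inter-ring links; ``None`` means a third of
        ``intra_coupling``.
    ring_drive_corr
        Correlation of the VAR innovations within a ring (a shared
        ring-level drive). The benchmark regime this generator emulates
        has whole clusters co-activating, not just chains of lagged
        links; without a shared drive, nodes two steps apart on a ring
        would be conditionally (and nearly marginally) independent and
        no undirected estimator could group rings into clusters.
    neural_noise_sd
        Standard deviation of the VAR innovations (neural-level noise).
    signal_noise_sd
        Standard deviation of the additive observation noise
        (mean-signal-level noise).
    hrf_smoothing
        Convolve each node with a fixed double-gamma kernel before adding
        observation noise. Off by default.
    seed
        Single integer determining all randomness (topology and series).
    """

    n_rings: int = 10
    ring_size: int = 5
    n_timepoints: int = 200
    tr_seconds: float = 3.0
    self_coupling: float = 0.6
    intra_coupling: float = 0.35
    inter_links: int = 8
    inter_coupling: float | None = None
    ring_drive_corr: float = 0.3
    neural_noise_sd: float = 1.0
    signal_noise_sd: float = 0.9
    hrf_smoothing: bool = False
    seed: int = 0
    burn_in: int = 100

    def __post_init__(self) -> None:
        if self.n_rings < 1 or self.ring_size < 2:
            raise ValueError("need at least one ring of at least two nodes")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.intra_coupling < 1:
            raise ValueError("intra_coupling must lie in [0, 1)")
        if self.neural_noise_sd < 0 or self.signal_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.inter_links < 0:
            raise ValueError("inter_links must be non-negative")
        if not 0 <= self.ring_drive_corr < 1:
            raise ValueError("ring_drive_corr must lie in [0, 1)")

    @property
    def n_nodes(self) -> int:
        return self.n_rings * self.ring_size

    @property
    def effective_inter_coupling(self) -> float:
        if self.inter_coupling is None:
            return self.intra_coupling / 3.0
        return self.inter_coupling


def hrf_kernel(tr_seconds: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR.

    Response peak at 6 s, undershoot trough at 16 s, undershoot amplitude
    one sixth of the peak; the kernel is scaled to unit peak.
    """
    t = np.arange(0.0, duration + 1e-9, tr_seconds)
    h = _gamma_dist.pdf(t, a=7.0, scale=1.0) - _gamma_dist.pdf(t, a=17.0, scale=1.0) / 6.0
    return h / h.max()


def _build_topology(spec: RingNetworkSpec, rng: np.random.Generator) -> GroundTruthNetwork:
    n = spec.n_nodes
    adjacency = np.zeros((n, n), dtype=int)
    labels = np.repeat(np.arange(spec.n_rings), spec.ring_size)
    for r in range(spec.n_rings):
        base = r * spec.ring_size
        for k in range(spec.ring_size):
            adjacency[base + k, base + (k + 1) % spec.ring_size] = 1
    placed = 0
    while placed < spec.inter_links:
        i, j = rng.integers(0, n, size=2)
        if labels[i] == labels[j] or adjacency[i, j]:
            continue
        adjacency[i, j] = 1
        placed += 1
    return GroundTruthNetwork(adjacency, labels)


def _transition_matrix(spec: RingNetworkSpec, truth: GroundTruthNetwork) -> np.ndarray:
    n = spec.n_nodes
    labels = truth.true_labels
    T = spec.self_coupling * np.eye(n)
    src, dst = np.nonzero(truth.directed_adjacency)
    for i, j in zip(src, dst):
        w = spec.intra_coupling if labels[i] == labels[j] else spec.effective_inter_coupling
        T[j, i] += w  # z_j(t) receives from z_i(t-1)
    radius = float(np.max(np.abs(np.linalg.eigvals(T))))
    if radius >= 1.0:
        raise ValueError(
            f"unstable VAR transition matrix: spectral radius {radius:.4f} >= 1"
        )
    return T


def _simulate_series(
    spec: RingNetworkSpec,
    T: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = spec.n_nodes
    total = spec.n_timepoints + spec.burn_in
    z = np.zeros((total, n))
    if spec.neural_noise_sd > 0:
        rho = spec.ring_drive_corr
        own = rng.normal(size=(total, n))
        if rho > 0:
            shared = rng.normal(size=(total, spec.n_rings))[:, labels]
            own = np.sqrt(1.0 - rho) * own + np.sqrt(rho) * shared
        noise = spec.neural_noise_sd * own
    else:
        noise = np.zeros((total, n))
    for t in range(1, total):
        z[t] = T @ z[t - 1] + noise[t]
    z = z[spec.burn_in :]
    if spec.hrf_smoothing:
        kernel = hrf_kernel(spec.tr_seconds)
        z = np.apply_along_axis(
            lambda col: np.convolve(col, kernel)[: spec.n_timepoints], 0, z
        )
    if spec.signal_noise_sd > 0:
        z = z + rng.normal(0.0, spec.signal_noise_sd, size=z.shape)
    return z


def simulate_ring_network(
    spec: RingNetworkSpec, series_seed: int | None = None
) -> tuple[TimeSeriesMatrix, GroundTruthNetwork]:
    """Simulate one subject from the ring-cluster VAR(1) model.

    The topology (including the random inter-ring links) is drawn from
    ``spec.seed`` alone, so different ``series_seed`` values produce
    independent realizations of the same ground-truth network.

    Returns the raw (not yet normalized) d x n series and the ground truth.
    """
    topo_rng = np.random.default_rng(spec.seed)
    truth = _build_topology(spec, topo_rng)
    T = _transition_matrix(spec, truth)
    if series_seed is None:
        series_seed = spec.seed
    series_rng = np.random.default_rng([spec.seed, series_seed])
    values = _simulate_series(spec, T, truth.true_labels, series_rng)
    return TimeSeriesMatrix(values), truth


def simulate_multisubject(
    spec: RingNetworkSpec, n_subjects: int, base_seed: int | None = None
) -> list[tuple[TimeSeriesMatrix, GroundTruthNetwork]]:
    """Independent per-subject realizations sharing one ground-truth topology.

    Subject i's series seed is ``base_seed + i`` (``base_seed`` defaults to
    ``spec.seed``), so a single integer reproduces the whole cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if base_seed is None:
        base_seed = spec.seed
    return [
        simulate_ring_network(spec, series_seed=base_seed + i)
        for i in range(n_subjects)
    ]


def simulate_correlated_groups(
    n_groups: int,
    group_size: int,
    T: int,
    within_corr: float,
    seed: int | None = None,
) -> TimeSeriesMatrix:
    """Gaussian series with block correlation structure (one factor per group).

    Each node is ``sqrt(rho) * f_g + sqrt(1 - rho) * e`` with the factor
    ``f_g`` shared within the group, giving pairwise within-group
    correlation rho = ``within_corr`` and zero across groups.
    """
    if not 0 <= within_corr < 1:
        raise ValueError("within_corr must lie in [0, 1)")
    if n_groups < 1 or group_size < 1 or T < 2:
        raise ValueError("need n_groups >= 1, group_size >= 1, T >= 2")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(T, n_groups))
    noise = rng.normal(size=(T, n_groups * group_size))
    shared = np.repeat(factors, group_size, axis=1)
    values = np.sqrt(within_corr) * shared + np.sqrt(1.0 - within_corr) * noise
    return TimeSeriesMatrix(values)


def _spec_with(spec: RingNetworkSpec, **kwargs) -> RingNetworkSpec:
    return replace(spec, **kwargs)
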