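"""Reading, writing and normalization of node time series and matrices.

File formats are plain delimited text (TSV by default, comma accepted):
one file per subject with a header row of node identifiers and one row per
time point. Association matrices are written as headered TSV. The netsim
simulation bundles (MAT v5) are read with :func:`scipy.io.loadmat`.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .containers import AssociationMatrix, GroundTruthNetwork, TimeSeriesMatrix

__all__ = [
    "normalize_node_series",
    "read_timeseries",
    "read_timeseries_dir",
    "write_timeseries",
    "write_subjects",
    "write_ground_truth",
    "read_netsim_mat",
    "read_association_matrix",
    "write_association_matrix",
]


def normalize_node_series(X_raw: TimeSeriesMatrix | np.ndarray) -> TimeSeriesMatrix:
    """Demean each node's series and scale it to unit l2 norm.

    The sparse-representation model assumes every column of the data matrix
    has unit norm; demeaning additionally ties the two-node case to the
    Pearson correlation coefficient (the inner product of two demeaned
    unit vectors is exactly r).

    Raises
    ------
    ValueError
        If any column is constant (zero variance), naming the node.
    """
    if isinstance(X_raw, TimeSeriesMatrix):
        values = X_raw.values
        node_ids = list(X_raw.node_ids)
    else:
        values = np.asarray(X_raw, dtype=float)
        node_ids = []
    centered = values - values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        ids = node_ids or [f"n{i + 1}" for i in range(values.shape[1])]
        raise ValueError(f"constant (zero-variance) column for node {ids[bad[0]]!r}")
    return TimeSeriesMatrix(centered / norms, node_ids=node_ids, normalized=True)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_timeseries(path: str | os.PathLike) -> TimeSeriesMatrix:
    """Read one subject's delimited time-series file (header = node IDs)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed time-series file {path.name}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: need at least 2 node columns")
    if df.isna().any().any():
        raise ValueError(f"{path.name}: ragged or missing values")
    return TimeSeriesMatrix(df.to_numpy(dtype=float), node_ids=[str(c) for c in df.columns])


def read_timeseries_dir(path: str | os.PathLike) -> list[TimeSeriesMatrix]:
    """Read every ``*.tsv``/``*.csv``/``*.txt`` file in a directory.

    Subjects are ordered by filename (lexicographic); all files must share
    the same node header.
    """
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".tsv", ".csv", ".txt"}
    )
    if not files:
        raise FileNotFoundError(f"no time-series files found in {path}")
    subjects = []
    for f in files:
        ts = read_timeseries(f)
        if subjects and ts.node_ids != subjects[0].node_ids:
            raise ValueError(
                f"{f.name}: node header differs from {files[0].name}"
            )
        subjects.append(ts)
    return subjects


def write_timeseries(ts: TimeSeriesMatrix, path: str | os.PathLike, sep: str = "\t") -> None:
    """Write one subject as delimited text with a node-ID header."""
    df = pd.DataFrame(ts.values, columns=ts.node_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_subjects(
    subjects: list[TimeSeriesMatrix], out_dir: str | os.PathLike, prefix: str = "subject"
) -> list[Path]:
    """Write one file per subject, zero-padded so filename order is subject order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(2, len(str(len(subjects))))
    paths = []
    for i, ts in enumerate(subjects, start=1):
        p = out_dir / f"{prefix}_{i:0{width}d}.tsv"
        write_timeseries(ts, p)
        paths.append(p)
    return paths


def write_ground_truth(truth: GroundTruthNetwork, out_dir: str | os.PathLike) -> None:
    """Write the directed edge list (``src<TAB>dst``, 1-based) and node labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    src, dst = np.nonzero(truth.directed_adjacency)
    with open(out_dir / "ground_truth_edges.tsv", "w") as fh:
        fh.write("src\tdst\n")
        for i, j in zip(src, dst):
            fh.write(f"{i + 1}\t{j + 1}\n")
    with open(out_dir / "ground_truth_labels.tsv", "w") as fh:
        fh.write("node\tcluster\n")
        for i, lab in enumerate(truth.true_labels):
            fh.write(f"{i + 1}\t{lab}\n")


def read_netsim_mat(
    path: str | os.PathLike, n_nodes: int, n_timepoints: int
) -> tuple[list[TimeSeriesMatrix], GroundTruthNetwork]:
    """Read a netsim-style MAT v5 bundle of simulated fMRI subjects.

    The bundle stores all subjects' time series stacked along the time axis
    in ``ts`` (subjects*n_timepoints rows, n_nodes columns) and the
    ground-truth network in ``net``: either one n_nodes x n_nodes weight
    matrix or a per-subject stack (n_subjects x n_nodes x n_nodes), in
    which case the first subject's network is used. A directed edge i -> j
    exists where the stored weight is nonzero.
    """
    mat = loadmat(path)
    if "ts" not in mat or "net" not in mat:
        raise ValueError("expected 'ts' and 'net' arrays in the MAT file")
    ts = np.asarray(mat["ts"], dtype=float)
    if ts.shape[1] != n_nodes:
        raise ValueError(f"expected {n_nodes} node columns, found {ts.shape[1]}")
    if ts.shape[0] % n_timepoints != 0:
        raise ValueError(
            f"{ts.shape[0]} rows not divisible by n_timepoints={n_timepoints}"
        )
    n_subjects = ts.shape[0] // n_timepoints
    net = np.asarray(mat["net"], dtype=float)
    if net.ndim == 3:
        net = net[0]
    if net.shape != (n_nodes, n_nodes):
        raise ValueError("ground-truth network shape mismatch")
    adjacency = (net != 0).astype(int)
    np.fill_diagonal(adjacency, 0)
    labels = _labels_from_adjacency(adjacency)
    truth = GroundTruthNetwork(adjacency, labels)
    node_ids = [f"n{i + 1}" for i in range(n_nodes)]
    subjects = [
        TimeSeriesMatrix(
            ts[s * n_timepoints : (s + 1) * n_timepoints], node_ids=list(node_ids)
        )
        for s in range(n_subjects)
    ]
    return subjects, truth


def _labels_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Connected components of the undirected skeleton, as integer labels."""
    from scipy.sparse.csgraph import connected_components

    und = ((adjacency != 0) | (adjacency.T != 0)).astype(int)
    _, labels = connected_components(und, directed=False)
    return labels


def write_association_matrix(A: AssociationMatrix, path: str | os.PathLike) -> None:
    """Write an association matrix as headered TSV (node IDs as row index)."""
    df = pd.DataFrame(A.values, index=A.node_ids, columns=A.node_ids)
    df.to_csv(path, sep="\t", index_label="node", float_format="%.17g")


def read_association_matrix(path: str | os.PathLike) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # undo asymmetric rounding from text round-trip
    return AssociationMatrix(values, node_ids=[str(c) for c in df.columns])
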