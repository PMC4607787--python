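"""End-to-end orchestration: data -> association matrices -> clusters -> metrics.

The pipeline mirrors the two-stage scheme the package implements: estimate
a whole-network association matrix per subject (sparse representation
and/or correlation baselines), identify sub-networks with affinity
propagation, and score the result. Everything is a pure function of
(config, seed): rerunning with the same configuration reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as asrio
from .ap import APConfig, preference_for_k
from .asr import SolverConfig, asr_association_matrix, select_lambda
from .baselines import partial_correlation_association, pearson_association
from .containers import AssociationMatrix, GroundTruthNetwork, TimeSeriesMatrix
from .metrics import (
    MetricsReport,
    align_global_mean,
    clustering_accuracy,
    modularity_communities,
    sensitivity,
    silhouette_similarity,
)
from .simulate import RingNetworkSpec, simulate_multisubject

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compare_estimators", "estimate_association"]

_ESTIMATORS = ("asr", "pearson", "partial")


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for one experiment run.

    ``source`` selects the input: ``simulate`` (built-in ring simulator),
    ``files`` (directory of per-subject delimited series) or ``netsim``
    (a MAT v5 bundle). ``lambda_policy`` is ``fixed`` (use ``lam``),
    ``grid-sensitivity`` or ``grid-modularity`` (per-subject grid search).
    """

    source: str = "simulate"
    input_path: str | None = None
    n_subjects: int = 10
    estimators: tuple[str, ...] = ("asr", "pearson")
    lam: float = 0.2
    lambda_policy: str = "fixed"
    solver: SolverConfig = field(default_factory=SolverConfig)
    k_target: int | None = 10
    ap: APConfig = field(default_factory=APConfig)
    metrics: tuple[str, ...] = ("sensitivity", "accuracy", "silhouette", "modularity")
    out_dir: str | None = None
    seed: int = 0
    sim: RingNetworkSpec = field(default_factory=RingNetworkSpec)
    netsim_nodes: int = 50
    netsim_timepoints: int = 200

    def __post_init__(self) -> None:
        if self.source not in {"simulate", "files", "netsim"}:
            raise ValueError(f"unknown source {self.source!r}")
        bad = set(self.estimators) - set(_ESTIMATORS)
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")
        if self.lambda_policy not in {"fixed", "grid-sensitivity", "grid-modularity"}:
            raise ValueError(f"unknown lambda policy {self.lambda_policy!r}")


def _load_subjects(
    cfg: PipelineConfig,
) -> tuple[list[TimeSeriesMatrix], GroundTruthNetwork | None]:
    if cfg.source == "simulate":
        spec = replace(cfg.sim, seed=cfg.seed)
        pairs = simulate_multisubject(spec, cfg.n_subjects)
        return [ts for ts, _ in pairs], pairs[0][1]
    if cfg.source == "files":
        if cfg.input_path is None:
            raise ValueError("source='files' requires input_path")
        return asrio.read_timeseries_dir(cfg.input_path), None
    if cfg.input_path is None:
        raise ValueError("source='netsim' requires input_path")
    subjects, truth = asrio.read_netsim_mat(
        cfg.input_path, cfg.netsim_nodes, cfg.netsim_timepoints
    )
    return subjects, truth


def estimate_association(
    X: TimeSeriesMatrix,
    estimator: str,
    solver: SolverConfig | None = None,
) -> AssociationMatrix:
    """Compute one association matrix with the named estimator.

    ``X`` must already be normalized for ``asr``; the correlation
    estimators accept raw series as well.
    """
    if estimator == "asr":
        A, _ = asr_association_matrix(X, solver or SolverConfig())
        return A
    if estimator == "pearson":
        return pearson_association(X)
    if estimator == "partial":
        return partial_correlation_association(X)
    raise ValueError(f"unknown estimator {estimator!r}")


def _subject_lambda(
    cfg: PipelineConfig, X: TimeSeriesMatrix, truth: GroundTruthNetwork | None
) -> float:
    if cfg.lambda_policy == "fixed":
        return cfg.lam
    criterion = "sensitivity" if cfg.lambda_policy == "grid-sensitivity" else "modularity"
    return select_lambda(
        X, ground_truth=truth, criterion=criterion, solver_config=cfg.solver
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full experiment described by ``cfg``.

    Returns a report dictionary with per-subject :class:`MetricsReport`
    objects per estimator, the group summary table, and the estimator
    comparison table. When ``cfg.out_dir`` is set, association matrices,
    cluster assignments, the summary, the comparison, the resolved config
    and a log are written there.
    """
    t0 = time.perf_counter()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    subjects_raw, truth = _load_subjects(cfg)
    logger.info("loaded %d subjects (source=%s)", len(subjects_raw), cfg.source)
    subjects = [asrio.normalize_node_series(ts) for ts in subjects_raw]

    reports: dict[str, list[MetricsReport]] = {e: [] for e in cfg.estimators}
    rows = []
    for s_idx, X in enumerate(subjects):
        t_subj = time.perf_counter()
        mats: dict[str, AssociationMatrix] = {}
        solver = cfg.solver
        asr_diagnostics = None
        if "asr" in cfg.estimators:
            lam_s = _subject_lambda(cfg, X, truth)
            solver = replace(cfg.solver, lam=lam_s)
        for est in cfg.estimators:
            if est == "asr":
                mats[est], W = asr_association_matrix(X, solver)
                asr_diagnostics = W.diagnostics
            else:
                mats[est] = estimate_association(X, est, solver)
        if out_dir and asr_diagnostics is not None:
            with open(out_dir / f"subject_{s_idx + 1:03d}_asr_solver.jsonl", "w") as fh:
                for rec in asr_diagnostics:
                    fh.write(json.dumps(rec, sort_keys=True) + "\n")

        aligned = (
            dict(zip(mats, align_global_mean(list(mats.values()))))
            if len(mats) > 1
            else {e: m.values for e, m in mats.items()}
        )

        for est in cfg.estimators:
            A = mats[est]
            report = MetricsReport()
            assignment = None
            if cfg.k_target is not None:
                _, assignment = preference_for_k(A, cfg.k_target, config=cfg.ap)
            if "sensitivity" in cfg.metrics and truth is not None:
                report.sensitivity = sensitivity(A, truth)
            if "accuracy" in cfg.metrics and truth is not None and assignment is not None:
                report.accuracy = clustering_accuracy(
                    assignment.labels, truth.true_labels
                )
            if (
                "silhouette" in cfg.metrics
                and assignment is not None
                and assignment.n_clusters >= 2
            ):
                _, report.silhouette_mean = silhouette_similarity(
                    aligned[est], assignment.labels
                )
            if "modularity" in cfg.metrics:
                q, _, n_comm = modularity_communities(A, seed=cfg.seed)
                report.modularity_Q = q
                report.n_communities = n_comm
            if assignment is not None:
                report.details["n_clusters"] = assignment.n_clusters
                report.details["ap_converged"] = bool(assignment.converged)
            reports[est].append(report)
            rows.append({"subject": s_idx + 1, "estimator": est, **report.as_dict()})

            if out_dir:
                asrio.write_association_matrix(
                    A, out_dir / f"subject_{s_idx + 1:03d}_{est}_association.tsv"
                )
                if assignment is not None:
                    pd.DataFrame(
                        {"node_id": A.node_ids, "cluster_id": assignment.labels}
                    ).to_csv(
                        out_dir / f"subject_{s_idx + 1:03d}_{est}_clusters.tsv",
                        sep="\t",
                        index=False,
                    )
        logger.info(
            "subject %d/%d done in %.1fs",
            s_idx + 1,
            len(subjects),
            time.perf_counter() - t_subj,
        )

    summary = pd.DataFrame(rows)
    comparison = compare_estimators(reports)
    result = {"reports": reports, "summary": summary, "comparison": comparison}

    if out_dir:
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.12g")
        comparison.to_csv(
            out_dir / "comparison.tsv", sep="\t", index=False, float_format="%.12g"
        )
        resolved = asdict(cfg)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(resolved, fh, indent=2, default=str, sort_keys=True)
        with open(out_dir / "log.txt", "w") as fh:
            fh.write(
                f"subjects={len(subjects)} estimators={','.join(cfg.estimators)} "
                f"seed={cfg.seed}\n"
            )
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return result


def compare_estimators(reports: dict[str, list[MetricsReport]]) -> pd.DataFrame:
    """Group summary per estimator plus paired per-subject differences.

    Each row is (metric, estimator) with mean/median/sd over subjects;
    additional rows give mean paired differences between estimator pairs
    for every metric both report on every subject.
    """
    sizes = {len(v) for v in reports.values()}
    if len(sizes) != 1:
        raise ValueError("estimators report on different subject sets")
    metric_names = ("sensitivity", "accuracy", "silhouette_mean", "modularity_Q")
    rows = []
    per_metric: dict[str, dict[str, np.ndarray]] = {}
    for metric in metric_names:
        per_metric[metric] = {}
        for est, reps in reports.items():
            vals = [getattr(r, metric) for r in reps]
            if any(v is None for v in vals):
                continue
            arr = np.asarray(vals, dtype=float)
            per_metric[metric][est] = arr
            rows.append(
                {
                    "metric": metric,
                    "estimator": est,
                    "mean": arr.mean(),
                    "median": float(np.median(arr)),
                    "sd": arr.std(ddof=1) if arr.size > 1 else 0.0,
                }
            )
    ests = list(reports)
    for metric, by_est in per_metric.items():
        for i, e1 in enumerate(ests):
            for e2 in ests[i + 1 :]:
                if e1 in by_est and e2 in by_est:
                    diff = by_est[e1] - by_est[e2]
                    rows.append(
                        {
                            "metric": metric,
                            "estimator": f"{e1}-{e2}",
                            "mean": diff.mean(),
                            "median": float(np.median(diff)),
                            "sd": diff.std(ddof=1) if diff.size > 1 else 0.0,
                        }
                    )
    return pd.DataFrame(rows, columns=["metric", "estimator", "mean", "median", "sd"])
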