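"""End-to-end orchestration: simulate -> topology -> networks -> classify.

A run is fully described by a :class:`RunConfig`; reruns with the same
config and seeds are bit-identical.  ``compare_modes`` evaluates several
network variants (partial / group-partial / sice / group-sice) on the same
cohort with shared fold order and classifier seed, the way the method
comparison table of the framework is meant to be read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    MODES,
    CVResult,
    MetricsReport,
    compute_metrics,
    connection_frequency,
    nested_loocv,
)
from .network import assemble_connectivity, build_subnetworks, full_partial_network
from .network import graphical_lasso, sample_covariance
from .panel import TimeSeriesPanel, read_panel, write_panel
from .synthetic import make_two_group_cohort
from .topology import TopologySelection, select_topology

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "run_pipeline",
    "compare_modes",
    "convergence_report",
    "evaluate_mode",
]

log = logging.getLogger("groupsice")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Either ``input_dir`` points at a panel written by
    :func:`groupsice.panel.write_panel`, or ``simulate`` holds keyword
    arguments for :func:`groupsice.synthetic.make_two_group_cohort` (a seeded
    two-group planted-difference cohort).
    """

    mode: str = "group-sice"
    output_dir: str = "runs/out"
    input_dir: str | None = None
    simulate: dict | None = None
    phi_grid: list | None = None
    lambda_pool: list | None = None
    topology_scope: str = "all_subjects"
    topology_tol: float = 1e-6
    topology_max_iter: int = 100
    sice_tol: float = 1e-6
    sice_max_iter: int = 200
    seed: int = 0
    classifier_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.topology_scope not in ("all_subjects", "train_only"):
            raise ValueError("topology_scope must be 'all_subjects' or 'train_only'")
        if self.input_dir is None and self.simulate is None:
            self.simulate = {}
        if self.input_dir is not None and self.simulate is not None:
            raise ValueError("give either input_dir or simulate, not both")

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ComparisonReport:
    """Per-mode metrics on one shared cohort (same folds, same seeds)."""

    table: pd.DataFrame
    results: dict
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _load_or_simulate(cfg: RunConfig) -> TimeSeriesPanel:
    if cfg.input_dir is not None:
        log.info("stage=load input=%s", cfg.input_dir)
        return read_panel(cfg.input_dir)
    kwargs = dict(cfg.simulate or {})
    kwargs.setdefault("seed", cfg.seed)
    log.info("stage=simulate %s", kwargs)
    return make_two_group_cohort(**kwargs)


def evaluate_mode(
    panel: TimeSeriesPanel,
    cfg: RunConfig,
    mode: str,
    selection: TopologySelection | None = None,
    trace_collector: list | None = None,
) -> tuple[MetricsReport, CVResult, TopologySelection | None]:
    """Run topology (if the mode needs it) and nested LOOCV for one variant."""
    needs_topology = mode in ("group-partial", "group-sice")
    if needs_topology and cfg.topology_scope == "all_subjects" and selection is None:
        t0 = time.perf_counter()
        selection = select_topology(
            panel,
            phi_grid=cfg.phi_grid,
            tol=cfg.topology_tol,
            max_iter=cfg.topology_max_iter,
        )
        log.info(
            "stage=topology mode=%s P=%d M=%d elapsed=%.2fs",
            mode, panel.P, panel.M, time.perf_counter() - t0,
        )
    t0 = time.perf_counter()
    cv = nested_loocv(
        panel,
        mode=mode,
        lambda_pool=cfg.lambda_pool,
        selection=selection if needs_topology else None,
        topology_scope=cfg.topology_scope,
        phi_grid=cfg.phi_grid,
        classifier_seed=cfg.classifier_seed,
        sice_tol=cfg.sice_tol,
        sice_max_iter=cfg.sice_max_iter,
        topology_tol=cfg.topology_tol,
        topology_max_iter=cfg.topology_max_iter,
        trace_collector=trace_collector,
    )
    log.info("stage=loocv mode=%s elapsed=%.2fs", mode, time.perf_counter() - t0)
    return compute_metrics(cv), cv, selection


def _representative_lambda(cv: CVResult):
    lams = [l for l in cv.chosen_lambda if l is not None]
    if not lams:
        return None
    vals, counts = np.unique(lams, return_counts=True)
    return float(vals[np.argmax(counts)])


def _write_networks(
    panel: TimeSeriesPanel,
    cfg: RunConfig,
    mode: str,
    selection: TopologySelection | None,
    lam,
    directory: Path,
) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for m, sid in enumerate(panel.subject_ids):
        if mode == "partial":
            theta = full_partial_network(panel, None, m).theta_full
        elif mode == "group-partial":
            theta = full_partial_network(panel, selection, m).theta_full
        elif mode == "sice":
            theta = graphical_lasso(
                sample_covariance(panel.subjects[m]),
                lam,
                tol=cfg.sice_tol,
                max_iter=cfg.sice_max_iter,
            ).theta
        else:  # group-sice
            subnets = [
                build_subnetworks(
                    panel, selection, p, lam, tol=cfg.sice_tol,
                    max_iter=cfg.sice_max_iter,
                )[m]
                for p in range(panel.P)
            ]
            theta = assemble_connectivity(subnets, panel.P).theta_full
        df = pd.DataFrame(theta, columns=panel.roi_names, index=panel.roi_names)
        df.to_csv(directory / f"{sid}_connectivity.tsv", sep="\t", float_format="%.10g")
        q, p = np.nonzero(theta)
        pd.DataFrame(
            {
                "source": [panel.roi_names[i] for i in q],
                "target": [panel.roi_names[j] for j in p],
                "weight": theta[q, p],
            }
        ).to_csv(
            directory / f"{sid}_edges.tsv", sep="\t", index=False,
            float_format="%.10g",
        )


def convergence_report(trace_collector: list, group_traces: dict | None = None) -> dict:
    """Summaries of the recorded iteration traces.

    ``trace_collector`` holds (n_iter, delta_theta_trace) tuples from the
    sparse estimator; ``group_traces`` maps target index -> delta-beta trace
    from the topology stage.  Returns terminal values, iteration-count
    statistics, and long-form trace tables ready to plot.
    """
    out: dict = {}
    if trace_collector:
        iters = np.array([n for n, _ in trace_collector])
        terminals = np.array(
            [t[-1] if len(t) else 0.0 for _, t in trace_collector]
        )
        out["sice"] = {
            "n_runs": int(len(iters)),
            "max_iterations": int(iters.max()),
            "mean_iterations": float(iters.mean()),
            "max_terminal_delta_theta": float(terminals.max()),
        }
        out["sice_trace_table"] = pd.DataFrame(
            [
                {"run": r, "iteration": i + 1, "delta_theta": float(v)}
                for r, (_, t) in enumerate(trace_collector)
                for i, v in enumerate(t)
            ]
        )
    if group_traces:
        terminals = np.array(
            [t[-1] if len(t) else 0.0 for t in group_traces.values()]
        )
        out["group"] = {
            "n_runs": int(len(group_traces)),
            "max_terminal_delta_beta": float(terminals.max()),
            "mean_terminal_delta_beta": float(terminals.mean()),
        }
        out["group_trace_table"] = pd.DataFrame(
            [
                {"target": p, "iteration": i + 1, "delta_beta": float(v)}
                for p, t in group_traces.items()
                for i, v in enumerate(t)
            ]
        )
    return out


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages for ``cfg.mode`` and write every artifact.

    Artifacts: resolved config YAML, the panel (if simulated) plus ground
    truth, topology JSON (group modes), per-subject connectivity TSVs at the
    most frequently chosen penalty, metrics JSON, ROC points CSV, connection
    frequency TSV, and convergence summaries.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    panel = _load_or_simulate(cfg)
    if cfg.input_dir is None:
        write_panel(panel, outdir / "panel")
    traces: list = []
    metrics, cv, selection = evaluate_mode(
        panel, cfg, cfg.mode, trace_collector=traces
    )
    if selection is not None:
        _json_dump(selection.to_json_dict(), outdir / "topology.json")
    lam_repr = _representative_lambda(cv)
    _write_networks(panel, cfg, cfg.mode, selection, lam_repr, outdir / "networks")
    _json_dump(
        {
            "mode": cfg.mode,
            "metrics": metrics.to_dict(),
            "chosen_lambda_per_fold": cv.chosen_lambda,
            "representative_lambda": lam_repr,
            "predictions": {
                sid: int(p)
                for sid, p in zip(cv.subject_ids, cv.outer_predictions)
            },
            "seed": cfg.seed,
            "classifier_seed": cfg.classifier_seed,
        },
        outdir / "metrics.json",
    )
    pd.DataFrame(metrics.roc_points, columns=["fpr", "tpr"]).to_csv(
        outdir / "roc_points.csv", index=False
    )
    connection_frequency(cv, roi_names=panel.roi_names).to_csv(
        outdir / "connection_frequency.tsv", sep="\t", index=False
    )
    conv = convergence_report(
        traces, selection.delta_traces if selection is not None else None
    )
    summary = {k: v for k, v in conv.items() if not k.endswith("_table")}
    _json_dump(summary, outdir / "convergence.json")
    for key in ("sice_trace_table", "group_trace_table"):
        if key in conv:
            conv[key].to_csv(outdir / f"{key}.csv", index=False)
    log.info("stage=done outdir=%s acc=%.2f", outdir, metrics.acc)
    return outdir


def compare_modes(cfg: RunConfig, modes=None) -> ComparisonReport:
    """Evaluate several network variants on the identical cohort.

    All modes share the panel, the LOOCV fold order (subject order), the
    classifier seed, and — for the two group-constrained modes — the same
    detected topology.  A failing mode is recorded and the others continue.
    """
    modes = list(modes) if modes else list(MODES)
    panel = _load_or_simulate(cfg)
    shared_selection: TopologySelection | None = None
    results: dict = {}
    errors: dict = {}
    rows = []
    for mode in modes:
        try:
            needs_topology = mode in ("group-partial", "group-sice")
            if (
                needs_topology
                and cfg.topology_scope == "all_subjects"
                and shared_selection is None
            ):
                shared_selection = select_topology(
                    panel,
                    phi_grid=cfg.phi_grid,
                    tol=cfg.topology_tol,
                    max_iter=cfg.topology_max_iter,
                )
            metrics, cv, _ = evaluate_mode(
                panel, cfg, mode, selection=shared_selection
            )
            results[mode] = {"metrics": metrics, "cv": cv}
            rows.append(
                {
                    "mode": mode,
                    "acc": metrics.acc,
                    "sen": metrics.sen,
                    "spe": metrics.spe,
                    "auc": metrics.auc,
                }
            )
        except Exception as exc:  # keep going; record the failure
            log.error("mode=%s failed: %s", mode, exc)
            errors[mode] = str(exc)
    table = pd.DataFrame(rows).set_index("mode") if rows else pd.DataFrame()
    return ComparisonReport(
        table=table,
        results=results,
        errors=errors,
        provenance={
            "M": panel.M,
            "P": panel.P,
            "n_t": panel.n_t,
            "seed": cfg.seed,
            "classifier_seed": cfg.classifier_seed,
        },
    )
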