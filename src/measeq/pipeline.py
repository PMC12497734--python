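"""End-to-end orchestration: per-condition analysis and baseline comparisons.

``analyze_condition`` runs burst/network-burst detection, activation-sequence
statistics, and TSPE connectivity on one recording.  ``run_condition_comparison``
applies it to a baseline recording, a treatment condition, and an optional
washout, and assembles the comparison tables: run-length cumulative
distributions per condition with KS comparisons, activity-metric summaries,
and connectivity variation versus baseline.  A ``RunManifest`` records every
parameter, seed, and input digest so a run can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .bursts import (ActivityMetrics, NetworkBurst, active_electrodes,
                     compute_activity_metrics, detect_all_bursts,
                     detect_network_bursts)
from .connectivity import (ConnectivityGraph, VariationSummary, attach_ci0,
                           filter_edges, surrogate_weight_threshold, tspe,
                           variation_vs_baseline)
from .io_core import RunConfig, SpikeTrainSet
from .sequences import SequenceStats, extract_sequences, sequence_stats
from .stats import ks_two_sample

__all__ = ["ConditionResult", "RunManifest", "analyze_condition",
           "run_condition_comparison", "build_manifest"]


@dataclass
class ConditionResult:
    metrics: ActivityMetrics
    n_bursts: int
    network_bursts: list[NetworkBurst]
    sequences: list
    seq_stats: SequenceStats | None
    graph: ConnectivityGraph


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    python_version: str
    input_digests: dict[str, str]
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def build_manifest(config: RunConfig, seed: int,
                   inputs: dict[str, str | Path] | None = None) -> RunManifest:
    digests = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        digests[name] = h.hexdigest()
    return RunManifest(config.to_dict(), seed, __version__,
                       platform.python_version(), digests)


def analyze_condition(sts: SpikeTrainSet, config: RunConfig | None = None,
                      seed: int = 0,
                      compute_connectivity: bool = True,
                      surrogate_threshold: bool = False) -> ConditionResult:
    """Run the full analysis chain on one recording.

    The surrogate weight threshold is optional because it multiplies the
    TSPE cost by the surrogate count; spatial and physiological filters are
    always applied.
    """
    cfg = config or RunConfig()
    bursts = detect_all_bursts(sts, cfg.bursts.max_isi_s, cfg.bursts.min_spikes)
    nbs = detect_network_bursts(sts, bursts, cfg.bursts.nb_min_fraction,
                                cfg.bursts.nb_merge_s,
                                cfg.bursts.active_mfr_threshold,
                                cfg.bursts.participation_base)
    metrics = compute_activity_metrics(sts, bursts, cfg.bursts.active_mfr_threshold)
    seqs = extract_sequences(nbs, sts, cfg.sequences.kernel_sd_ms,
                             cfg.sequences.bin_ms,
                             full_only=cfg.sequences.full_sequences_only)
    stats = None
    if len(seqs) >= 2:
        stats = sequence_stats(seqs, n_iter=cfg.sequences.mc_iterations, seed=seed,
                               include_singleton_runs=cfg.sequences.include_singleton_runs)

    graph = ConnectivityGraph(sts.layout, ())
    if compute_connectivity and sum(
            sts.spikes[e].size >= cfg.connectivity.min_spikes_per_train
            for e in sts.layout.electrodes) >= 2:
        graph = tspe(sts, cfg.connectivity)
        thr = None
        if surrogate_threshold and cfg.connectivity.n_surrogates > 0:
            thr = surrogate_weight_threshold(sts, cfg.connectivity, seed=seed + 1)
        graph = filter_edges(graph, cfg.connectivity.speed_bounds_m_s,
                             cfg.connectivity.latency_bounds_ms, thr)
        graph = attach_ci0(graph, sts, cfg.connectivity)
    return ConditionResult(metrics, len(bursts), nbs, seqs, stats, graph)


def _metric_summary(m: ActivityMetrics) -> dict:
    act = [e for e, f in m.active.items() if f]
    return {
        "n_active_electrodes": len(act),
        "mean_mfr": float(np.mean([m.mfr[e] for e in act])) if act else 0.0,
        "mean_mbr": float(np.mean([m.mbr[e] for e in act])) if act else 0.0,
        "mean_bd": float(np.mean(m.burst_durations)) if m.burst_durations else 0.0,
        "mean_ibi": float(np.mean(m.inter_burst_intervals)) if m.inter_burst_intervals else 0.0,
    }


def _run_length_cdf(runs: Sequence[int]) -> list[tuple[int, float]]:
    if not runs:
        return []
    runs = np.asarray(sorted(runs))
    out = []
    for v in np.unique(runs):
        out.append((int(v), float(np.mean(runs <= v))))
    return out


def run_condition_comparison(baseline: SpikeTrainSet,
                             condition: SpikeTrainSet,
                             washout: SpikeTrainSet | None = None,
                             config: RunConfig | None = None,
                             seed: int = 0,
                             compute_connectivity: bool = True,
                             surrogate_threshold: bool = False) -> dict:
    """Baseline / treatment (/ washout) comparison report.

    Returns a nested dict with per-condition metric summaries, run-length
    lists and cumulative distributions, pairwise KS comparisons of run
    lengths against baseline, and connectivity variation versus baseline.
    Deterministic given config and seed.
    """
    cfg = config or RunConfig()
    conditions: dict[str, SpikeTrainSet] = {"baseline": baseline, "condition": condition}
    if washout is not None:
        conditions["washout"] = washout
    for name, sts in conditions.items():
        if sts.layout.electrodes != baseline.layout.electrodes:
            raise ValueError(f"layout mismatch between baseline and {name}")

    results = {name: analyze_condition(sts, cfg, seed=seed + i,
                                       compute_connectivity=compute_connectivity,
                                       surrogate_threshold=surrogate_threshold)
               for i, (name, sts) in enumerate(conditions.items())}

    report: dict = {"conditions": {}, "comparisons": {}}
    for name, res in results.items():
        runs = res.seq_stats.runs if res.seq_stats else []
        report["conditions"][name] = {
            "metrics": _metric_summary(res.metrics),
            "n_network_bursts": len(res.network_bursts),
            "n_sequences": len(res.sequences),
            "run_lengths": runs,
            "run_length_cdf": _run_length_cdf(runs),
            "mean_run_length": float(np.mean(runs)) if runs else 0.0,
            "shannon_h": res.seq_stats.shannon_h if res.seq_stats else None,
            "equitability_j": res.seq_stats.equitability_j if res.seq_stats else None,
            "n_edges": len(res.graph.edges),
        }

    base = results["baseline"]
    for name, res in results.items():
        if name == "baseline":
            continue
        comp: dict = {}
        if base.seq_stats and res.seq_stats and base.seq_stats.runs and res.seq_stats.runs:
            ks = ks_two_sample(res.seq_stats.runs, base.seq_stats.runs)
            comp["run_length_ks_d"] = ks.statistic
            comp["run_length_ks_p"] = ks.p
        base_m = _metric_summary(base.metrics)
        cond_m = _metric_summary(res.metrics)
        comp["mfr_variation_pct"] = (
            100.0 * (cond_m["mean_mfr"] - base_m["mean_mfr"]) / base_m["mean_mfr"]
            if base_m["mean_mfr"] > 0 else None)
        if compute_connectivity:
            comp["connectivity_variation"] = asdict(
                variation_vs_baseline(base.graph, res.graph))
        report["comparisons"][name] = comp
    return report
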