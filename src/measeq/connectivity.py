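"""Directed functional connectivity from spike trains.

Connectivity is estimated with the Total Spiking Probability Edges (TSPE)
approach: for every ordered electrode pair the normalised cross-correlogram
is scanned with a family of peak/edge filters (a central running-average
plateau flanked by negative background windows, over a grid of window sizes);
the signed extremum of the summed filtered correlogram over candidate delays
is the connection weight (positive = putative excitation, negative =
inhibition) and its location is the best delay.  Edges are then pruned by a
spatial filter (plausible propagation speed given electrode distance), a
physiological filter (synaptic latency bounds), and an optional
surrogate-based weight threshold.  Pairwise synchrony is quantified by the
coincidence index CI0: the fraction of cross-correlogram mass within +-1 ms
of zero lag over a +-100 ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_core import ConnectivityConfig, Layout, SpikeTrainSet

__all__ = [
    "Edge",
    "ConnectivityGraph",
    "VariationSummary",
    "cross_correlogram",
    "tspe",
    "tspe_pair_weight",
    "surrogate_weight_threshold",
    "filter_edges",
    "coincidence_index",
    "attach_ci0",
    "variation_vs_baseline",
]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float          # signed TSPE score
    delay_ms: float        # best delay
    label: str             # "intra" or "inter" from endpoint clusters
    ci0: float | None = None


@dataclass(frozen=True)
class ConnectivityGraph:
    layout: Layout
    edges: tuple[Edge, ...]

    def __post_init__(self):
        for e in self.edges:
            if e.source == e.target:
                raise ValueError("self-edges are not allowed")

    def subset(self, label: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.label == label)


@dataclass(frozen=True)
class VariationSummary:
    """Percent change of six connectivity summaries versus baseline.

    Entries are ``None`` (flagged undefined) when the baseline quantity is
    zero or missing, never silently zeroed.
    """

    inter_count_pct: float | None
    intra_count_pct: float | None
    inter_weight_pct: float | None
    intra_weight_pct: float | None
    inter_ci0_pct: float | None
    intra_ci0_pct: float | None


# ---------------------------------------------------------------------------
# Cross-correlogram machinery
# ---------------------------------------------------------------------------

def _pair_diffs(ti: np.ndarray, tj: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """All differences t_j - t_i that fall in [lo, hi), via sorted search."""
    left = np.searchsorted(tj, ti + lo, side="left")
    right = np.searchsorted(tj, ti + hi, side="left")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(left, counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return tj[starts + offsets] - np.repeat(ti, counts)


def cross_correlogram(ti: np.ndarray, tj: np.ndarray,
                      edges_s: np.ndarray) -> np.ndarray:
    """Counts of spike-time differences t_j - t_i in the given bin edges."""
    diffs = _pair_diffs(np.asarray(ti, float), np.asarray(tj, float),
                        float(edges_s[0]), float(edges_s[-1]))
    counts, _ = np.histogram(diffs, bins=edges_s)
    return counts


def _tspe_score(ti: np.ndarray, tj: np.ndarray, cfg: ConnectivityConfig
                ) -> tuple[float, float]:
    """TSPE weight and best delay (ms) for one ordered pair."""
    bin_s = cfg.bin_ms / 1000.0
    max_d = int(round(cfg.max_delay_ms / cfg.bin_ms))
    a_set = tuple(int(a) for a in cfg.averaging_windows)
    b_set = tuple(int(b) for b in cfg.edge_windows)
    c_set = tuple(int(c) for c in cfg.crossing_windows)
    margin = max(a // 2 + c + b for a in a_set for b in b_set for c in c_set) \
        + max(a - a // 2 for a in a_set) + 1

    d_lo, d_hi = 1 - margin, max_d + margin
    # bins centred on integer delays d_lo .. d_hi
    edges = (np.arange(d_lo, d_hi + 2) - 0.5) * bin_s
    counts = cross_correlogram(ti, tj, edges).astype(float)
    c_norm = counts / ti.size  # spiking probability of j given an i spike

    csum = np.concatenate([[0.0], np.cumsum(c_norm)])

    def wmean(start_idx: np.ndarray, width: int) -> np.ndarray:
        # mean of c_norm[start : start+width] (array index space)
        if width <= 0:
            return np.zeros_like(start_idx, dtype=float)
        return (csum[start_idx + width] - csum[start_idx]) / width

    d = np.arange(1, max_d + 1)
    pos = d - d_lo                      # array index of delay d
    score = np.zeros(d.size)
    for a in a_set:
        a2 = a // 2
        plateau = wmean(pos - a2, a)
        for b in b_set:
            for c in c_set:
                left = wmean(pos - a2 - c - b, b)
                right = wmean(pos - a2 + a + c, b)
                score += plateau - 0.5 * (left + right)

    k = int(np.argmax(np.abs(score)))
    best = score[k]
    # tie-break among equal-magnitude extrema: the delay with the most
    # extreme raw correlogram value, then the earliest
    ties = np.nonzero(np.isclose(np.abs(score), np.abs(best), rtol=1e-9, atol=0))[0]
    if ties.size > 1:
        raw = c_norm[pos[ties]]
        k = int(ties[int(np.argmax(raw))] if best >= 0 else ties[int(np.argmin(raw))])
        best = score[k]
    return float(best), float(d[k] * cfg.bin_ms)


def tspe_pair_weight(ti: np.ndarray, tj: np.ndarray,
                     cfg: ConnectivityConfig | None = None) -> tuple[float, float]:
    """Convenience wrapper: TSPE weight and best delay for two raw trains."""
    return _tspe_score(np.asarray(ti, float), np.asarray(tj, float),
                       cfg or ConnectivityConfig())


def _edge_label(layout: Layout, a: str, b: str) -> str:
    return "intra" if layout.clusters[a] == layout.clusters[b] else "inter"


def tspe(sts: SpikeTrainSet, cfg: ConnectivityConfig | None = None) -> ConnectivityGraph:
    """Unfiltered TSPE graph over all ordered pairs of sufficiently active electrodes.

    Pairs in which either train has fewer than ``min_spikes_per_train``
    spikes are skipped with a warning (their correlograms are too sparse for
    a meaningful estimate).
    """
    cfg = cfg or ConnectivityConfig()
    usable = [e for e in sts.layout.electrodes
              if sts.spikes[e].size >= cfg.min_spikes_per_train]
    skipped = len(sts.layout.electrodes) - len(usable)
    if skipped:
        warnings.warn(f"{skipped} electrode(s) below {cfg.min_spikes_per_train} "
                      "spikes skipped in TSPE")
    if len(usable) < 2:
        raise ValueError("need at least 2 sufficiently active electrodes")
    edges = []
    for src in usable:
        for tgt in usable:
            if src == tgt:
                continue
            w, delay = _tspe_score(sts.spikes[src], sts.spikes[tgt], cfg)
            edges.append(Edge(src, tgt, w, delay, _edge_label(sts.layout, src, tgt)))
    return ConnectivityGraph(sts.layout, tuple(edges))


def surrogate_weight_threshold(sts: SpikeTrainSet,
                               cfg: ConnectivityConfig | None = None,
                               n_surrogates: int | None = None,
                               seed: int = 0) -> float:
    """Pooled jitter-surrogate threshold on |weight|.

    Every train is jittered uniformly by +-``surrogate_jitter_ms``; TSPE runs
    on the jittered set and all |weights| are pooled across surrogates; the
    threshold is the configured percentile of that pooled null.  Jittering
    destroys millisecond-scale spike timing while preserving rates and slow
    covariations, so weights above the threshold reflect fine timing
    structure rather than rate co-modulation.
    """
    cfg = cfg or ConnectivityConfig()
    n_sur = cfg.n_surrogates if n_surrogates is None else n_surrogates
    if n_sur <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    jit = cfg.surrogate_jitter_ms / 1000.0
    pooled: list[float] = []
    for _ in range(n_sur):
        trains = {}
        for e in sts.layout.electrodes:
            t = sts.spikes[e]
            t = np.sort(np.clip(t + rng.uniform(-jit, jit, size=t.size),
                                0, sts.duration))
            # enforce strict monotonicity after jitter
            for i in range(1, t.size):
                if t[i] <= t[i - 1]:
                    t[i] = t[i - 1] + 1e-6
            trains[e] = t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = tspe(SpikeTrainSet(sts.layout, trains, sts.duration), cfg)
        pooled.extend(abs(e.weight) for e in g.edges)
    return float(np.percentile(pooled, cfg.surrogate_percentile))


def filter_edges(g: ConnectivityGraph,
                 speed_bounds_m_s: tuple[float, float] | None = (0.02, 2.0),
                 latency_bounds_ms: tuple[float, float] | None = (1.0, 25.0),
                 weight_threshold: float | None = None) -> ConnectivityGraph:
    """Prune implausible edges; deterministic and idempotent.

    * spatial: electrode distance / best delay must fall inside the
      propagation-speed bounds (m/s);
    * physiological: best delay must fall inside the synaptic latency
      bounds (ms);
    * significance: |weight| must reach ``weight_threshold`` (typically a
      surrogate-null percentile).
    Passing ``None`` disables the corresponding filter.
    """
    layout = g.layout
    kept = []
    for e in g.edges:
        if latency_bounds_ms is not None:
            if not latency_bounds_ms[0] <= e.delay_ms <= latency_bounds_ms[1]:
                continue
        if speed_bounds_m_s is not None and e.delay_ms > 0:
            dist_um = layout.distance_um(e.source, e.target)
            speed = dist_um / e.delay_ms * 1e-3  # um/ms -> m/s
            if not speed_bounds_m_s[0] <= speed <= speed_bounds_m_s[1]:
                continue
        if weight_threshold is not None and abs(e.weight) < weight_threshold:
            continue
        kept.append(e)
    return ConnectivityGraph(layout, tuple(kept))


# ---------------------------------------------------------------------------
# Coincidence index
# ---------------------------------------------------------------------------

def coincidence_index(train_i: np.ndarray, train_j: np.ndarray,
                      sync_halfwidth_ms: float = 1.0,
                      lag_halfwidth_ms: float = 100.0,
                      bin_ms: float = 0.5) -> float:
    """CI0: cross-correlogram mass within +-sync_halfwidth over its total mass.

    The correlogram spans +-``lag_halfwidth_ms`` at ``bin_ms`` resolution
    with bin edges symmetric about zero lag, so CI0 is symmetric under train
    exchange.  Returns 0 when the correlogram is empty.
    """
    ti = np.asarray(train_i, float)
    tj = np.asarray(train_j, float)
    if ti.size == 0 or tj.size == 0:
        raise ValueError("coincidence index requires two non-empty trains")
    lag_s = lag_halfwidth_ms / 1000.0
    bin_s = bin_ms / 1000.0
    n_half = int(round(lag_halfwidth_ms / bin_ms))
    edges = np.arange(-n_half, n_half + 1) * bin_s
    counts = cross_correlogram(ti, tj, edges)
    total = counts.sum()
    if total == 0:
        return 0.0
    centres = (edges[:-1] + edges[1:]) / 2
    sync = np.abs(centres) <= sync_halfwidth_ms / 1000.0
    return float(counts[sync].sum() / total)


def attach_ci0(g: ConnectivityGraph, sts: SpikeTrainSet,
               cfg: ConnectivityConfig | None = None) -> ConnectivityGraph:
    """Return a copy of the graph with CI0 computed for every edge's pair."""
    cfg = cfg or ConnectivityConfig()
    cache: dict[frozenset, float] = {}
    edges = []
    for e in g.edges:
        key = frozenset((e.source, e.target))
        if key not in cache:
            cache[key] = coincidence_index(
                sts.spikes[e.source], sts.spikes[e.target],
                cfg.ci0_sync_halfwidth_ms, cfg.ci0_lag_halfwidth_ms, cfg.ci0_bin_ms)
        edges.append(replace(e, ci0=cache[key]))
    return ConnectivityGraph(g.layout, tuple(edges))


# ---------------------------------------------------------------------------
# Condition-versus-baseline variation
# ---------------------------------------------------------------------------

def _pct(base: float | None, cond: float | None) -> float | None:
    if base is None or cond is None or base == 0:
        return None
    return 100.0 * (cond - base) / base


def _summaries(g: ConnectivityGraph, label: str) -> tuple[float, float | None, float | None]:
    edges = g.subset(label)
    count = float(len(edges))
    weight = float(np.mean([abs(e.weight) for e in edges])) if edges else None
    ci_vals = [e.ci0 for e in edges if e.ci0 is not None]
    ci = float(np.mean(ci_vals)) if ci_vals else None
    return count, weight, ci


def variation_vs_baseline(g_base: ConnectivityGraph,
                          g_cond: ConnectivityGraph) -> VariationSummary:
    """Percent change of edge counts, mean |weight| and mean CI0, intra and inter."""
    if g_base.layout.electrodes != g_cond.layout.electrodes:
        raise ValueError("baseline and condition graphs use different layouts")
    b_inter, b_inter_w, b_inter_ci = _summaries(g_base, "inter")
    b_intra, b_intra_w, b_intra_ci = _summaries(g_base, "intra")
    c_inter, c_inter_w, c_inter_ci = _summaries(g_cond, "inter")
    c_intra, c_intra_w, c_intra_ci = _summaries(g_cond, "intra")
    return VariationSummary(
        inter_count_pct=_pct(b_inter, c_inter),
        intra_count_pct=_pct(b_intra, c_intra),
        inter_weight_pct=_pct(b_inter_w, c_inter_w),
        intra_weight_pct=_pct(b_intra_w, c_intra_w),
        inter_ci0_pct=_pct(b_inter_ci, c_inter_ci),
        intra_ci0_pct=_pct(b_intra_ci, c_intra_ci),
    )
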