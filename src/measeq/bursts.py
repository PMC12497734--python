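"""Electrode-level burst detection (string method), network bursts, and
the four activity metrics (MFR, MBR, BD, IBI).

A burst is a maximal string of at least ``min_spikes`` spikes whose
consecutive inter-spike intervals never exceed ``max_isi``.  A network burst
(NB) is a population event formed by merging electrode bursts that overlap or
fall within a short merge interval, provided a minimum fraction of the active
electrodes takes part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import BurstConfig, SpikeTrainSet

__all__ = [
    "Burst",
    "NetworkBurst",
    "ActivityMetrics",
    "detect_bursts_string",
    "detect_all_bursts",
    "active_electrodes",
    "detect_network_bursts",
    "compute_activity_metrics",
]


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    start: float
    end: float
    n_spikes: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("burst end before start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    electrodes: frozenset[str]
    cluster_spikes: dict[int, np.ndarray] = field(default_factory=dict, compare=False)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ActivityMetrics:
    mfr: dict[str, float]          # spikes/s per electrode
    active: dict[str, bool]        # MFR strictly above the activity threshold
    mbr: dict[str, float]          # bursts/min per electrode
    burst_durations: list[float]   # seconds, pooled over electrodes
    inter_burst_intervals: list[float]  # seconds, within-electrode end-to-next-start


def detect_bursts_string(train: np.ndarray, electrode_id: str = "",
                         max_isi: float = 0.1, min_spikes: int = 5) -> list[Burst]:
    """Partition a sorted train into maximal ISI-bounded strings; keep the long ones."""
    t = np.asarray(train, dtype=float)
    if t.size == 0:
        return []
    gaps = np.where(np.diff(t) > max_isi)[0]
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [t.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        count = e - s + 1
        if count >= min_spikes:
            out.append(Burst(electrode_id, float(t[s]), float(t[e]), int(count)))
    return out


def detect_all_bursts(sts: SpikeTrainSet, max_isi: float = 0.1,
                      min_spikes: int = 5) -> list[Burst]:
    bursts: list[Burst] = []
    for e in sts.layout.electrodes:
        bursts.extend(detect_bursts_string(sts.spikes[e], e, max_isi, min_spikes))
    return bursts


def active_electrodes(sts: SpikeTrainSet, mfr_threshold: float = 0.1) -> set[str]:
    """Electrodes whose mean firing rate strictly exceeds the threshold."""
    return {e for e in sts.layout.electrodes
            if sts.spikes[e].size / sts.duration > mfr_threshold}


def detect_network_bursts(
    sts: SpikeTrainSet,
    bursts: list[Burst],
    min_fraction: float = 0.20,
    merge_interval: float = 0.1,
    active_mfr_threshold: float = 0.1,
    participation_base: str = "active",
) -> list[NetworkBurst]:
    """Merge electrode bursts into population events and keep the well-attended ones.

    Bursts that overlap or whose gap is at most ``merge_interval`` join the
    same candidate event.  A candidate becomes a network burst when it
    involves at least ``min_fraction`` of the reference electrode pool —
    active electrodes by default, or all layout electrodes when
    ``participation_base == "all"``.
    """
    if participation_base == "active":
        base = active_electrodes(sts, active_mfr_threshold)
    elif participation_base == "all":
        base = set(sts.layout.electrodes)
    else:
        raise ValueError("participation_base must be 'active' or 'all'")
    if not base:
        warnings.warn("no active electrodes: no network bursts")
        return []

    ordered = sorted(bursts, key=lambda b: (b.start, b.end))
    candidates: list[list[Burst]] = []
    cur: list[Burst] = []
    cur_end = -np.inf
    for b in ordered:
        if cur and b.start - cur_end <= merge_interval:
            cur.append(b)
            cur_end = max(cur_end, b.end)
        else:
            if cur:
                candidates.append(cur)
            cur = [b]
            cur_end = b.end
    if cur:
        candidates.append(cur)

    nbs = []
    for group in candidates:
        members = frozenset(b.electrode_id for b in group)
        if len(members) / len(base) >= min_fraction:
            start = min(b.start for b in group)
            end = max(b.end for b in group)
            cl = {}
            for cid in sts.layout.cluster_ids:
                cl[cid] = sts.cluster_spikes(cid, start, end)
            nbs.append(NetworkBurst(start, end, members, cl))
    return nbs


def compute_activity_metrics(sts: SpikeTrainSet, bursts: list[Burst],
                             active_mfr_threshold: float = 0.1) -> ActivityMetrics:
    """MFR, activity flags, MBR, burst durations, and inter-burst intervals."""
    if sts.duration <= 0:
        raise ValueError("zero-duration recording")
    mfr = {e: sts.spikes[e].size / sts.duration for e in sts.layout.electrodes}
    active = {e: mfr[e] > active_mfr_threshold for e in sts.layout.electrodes}

    per_electrode: dict[str, list[Burst]] = {e: [] for e in sts.layout.electrodes}
    for b in bursts:
        per_electrode[b.electrode_id].append(b)

    minutes = sts.duration / 60.0
    mbr = {e: len(per_electrode[e]) / minutes for e in sts.layout.electrodes}
    bd = [b.duration for b in bursts]
    ibi = []
    for e, bs in per_electrode.items():
        bs = sorted(bs, key=lambda b: b.start)
        for prev, nxt in zip(bs, bs[1:]):
            ibi.append(nxt.start - prev.end)
    return ActivityMetrics(mfr, active, mbr, bd, ibi)
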