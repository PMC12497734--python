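"""Synthetic clustered MEA activity with known ground truth.

The generator emulates the phenomenology of a four-cluster cortical culture:
network bursts (NBs) recur at Poisson-like intervals; within each NB the four
clusters activate in an ordered sequence drawn from a motif repertoire whose
persistence is a first-order Markov repeat probability ``p_rep``; every
electrode fires a tight spike burst around its cluster's activation time; a
low-rate Poisson background runs throughout.  Directed connectivity can be
planted spike-by-spike, and voltage traces can be synthesised from a biphasic
spike template plus white Gaussian noise, giving every analysis stage a ground
truth to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import Layout, SpikeTrainSet, VoltageRecording

__all__ = [
    "GroundTruth",
    "PlantedConnection",
    "simulate_activity",
    "plant_connectivity",
    "synthesize_voltage",
    "simulate_dose_response",
    "default_biphasic_template",
]

# spikes closer than this are considered duplicates at I/O resolution
_DEDUP_RESOLUTION_S = 1e-4


@dataclass(frozen=True)
class PlantedConnection:
    """A directed planted connection between two electrodes."""

    source: str
    target: str
    sign: int                 # +1 excitatory (insertion), -1 inhibitory (deletion)
    delay_ms: float
    probability: float        # per-source-spike transfer / suppression probability
    suppression_window_ms: float = 5.0

    def __post_init__(self):
        if self.delay_ms <= 0:
            raise ValueError("delay must be positive")
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must be in [0, 1]")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    nb_onsets: np.ndarray                     # seconds
    sequences: list[tuple[int, ...]]          # ordered cluster ids per NB
    p_rep: float
    connections: list[PlantedConnection] = field(default_factory=list)
    background_rate: float = 0.0

    def __post_init__(self):
        if not 0 <= self.p_rep <= 1:
            raise ValueError("p_rep must be in [0, 1]")


def _dedup_sorted(t: np.ndarray, resolution: float = _DEDUP_RESOLUTION_S) -> np.ndarray:
    if t.size < 2:
        return t
    keep = np.empty(t.size, dtype=bool)
    keep[0] = True
    last = t[0]
    for i in range(1, t.size):
        if t[i] - last > resolution:
            keep[i] = True
            last = t[i]
        else:
            keep[i] = False
    return t[keep]


def simulate_activity(
    layout: Layout,
    duration: float = 600.0,
    nb_rate: float = 0.2,
    motif_repertoire: Sequence[Sequence[int]] | None = None,
    p_rep: float = 0.5,
    intra_cluster_lag_ms: float = 10.0,
    inter_cluster_lag_ms: float = 80.0,
    background_rate: float = 0.2,
    burst_spikes_per_electrode: int = 8,
    min_nb_separation: float = 1.0,
    seed: int = 0,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate clustered network activity with a known activation-sequence truth.

    NB onsets follow a renewal process with exponential inter-event gaps of
    rate ``nb_rate`` shifted by ``min_nb_separation`` (a Poisson process with
    a hard refractory floor keeping events resolvable).  Each NB's cluster
    activation sequence repeats the previous one with probability ``p_rep``,
    otherwise it is drawn uniformly from ``motif_repertoire``.  Within an NB,
    the cluster at sequence rank r activates ``r * inter_cluster_lag_ms``
    after onset; each member electrode fires ``burst_spikes_per_electrode``
    spikes (intra-burst ISIs of a few ms, well under the 100 ms burst cutoff)
    centred on the cluster time plus a Gaussian per-electrode jitter of SD
    ``intra_cluster_lag_ms``.  Background spikes are independent Poisson at
    ``background_rate`` per electrode.  All randomness derives from ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if nb_rate < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")
    if motif_repertoire is None:
        motif_repertoire = [(1, 2, 3, 4)]
    repertoire = [tuple(int(c) for c in m) for m in motif_repertoire]
    if not repertoire:
        raise ValueError("motif repertoire must be non-empty")
    if not 0 <= p_rep <= 1:
        raise ValueError("p_rep must be in [0, 1]")
    if nb_rate > 0 and nb_rate * min_nb_separation >= 1.0:
        raise ValueError(
            f"nb_rate {nb_rate}/s cannot respect the minimum separation "
            f"{min_nb_separation}s (infeasible packing)")

    rng = np.random.default_rng(seed)
    lag = inter_cluster_lag_ms / 1000.0
    jitter_sd = intra_cluster_lag_ms / 1000.0
    n_ranks = max((len(m) for m in repertoire), default=1)
    # keep whole NBs inside the recording
    tail_margin = n_ranks * lag + 0.3

    # --- NB onsets: shifted-exponential renewal keeps mean rate = nb_rate
    onsets: list[float] = []
    if nb_rate > 0 and duration > tail_margin + min_nb_separation:
        exp_rate = 1.0 / (1.0 / nb_rate - min_nb_separation)
        t = 0.5 + rng.exponential(1.0 / exp_rate)
        while t < duration - tail_margin:
            onsets.append(t)
            t += min_nb_separation + rng.exponential(1.0 / exp_rate)
    nb_onsets = np.asarray(onsets)

    # --- activation sequences: first-order Markov persistence
    sequences: list[tuple[int, ...]] = []
    for i in range(len(onsets)):
        if i > 0 and rng.random() < p_rep:
            sequences.append(sequences[-1])
        else:
            sequences.append(repertoire[rng.integers(len(repertoire))])

    # --- assemble spikes
    spikes: dict[str, list[np.ndarray]] = {e: [] for e in layout.electrodes}
    if background_rate > 0:
        for e in layout.electrodes:
            n_bg = rng.poisson(background_rate * duration)
            spikes[e].append(rng.uniform(0, duration, size=n_bg))

    nsp = int(burst_spikes_per_electrode)
    for onset, seq in zip(onsets, sequences):
        for rank, cluster in enumerate(seq):
            c_time = onset + rank * lag
            for e in layout.cluster_members(cluster):
                if nsp <= 0:
                    continue
                centre = c_time + rng.normal(0.0, jitter_sd)
                isis = rng.uniform(0.002, 0.006, size=max(nsp - 1, 0))
                rel = np.concatenate([[0.0], np.cumsum(isis)])
                ts = centre + rel - rel.mean()
                spikes[e].append(ts)

    trains: dict[str, np.ndarray] = {}
    for e in layout.electrodes:
        t = np.sort(np.concatenate(spikes[e])) if spikes[e] else np.empty(0)
        t = t[(t >= 0) & (t <= duration)]
        trains[e] = _dedup_sorted(t)

    sts = SpikeTrainSet(layout, trains, duration)
    truth = GroundTruth(nb_onsets=nb_onsets, sequences=sequences, p_rep=p_rep,
                        background_rate=background_rate)
    return sts, truth


def plant_connectivity(
    sts: SpikeTrainSet,
    connections: Sequence[PlantedConnection],
    seed: int = 0,
) -> SpikeTrainSet:
    """Superimpose directed connections on existing spike trains.

    For an excitatory connection each source spike triggers, with the stated
    transfer probability, a target spike at ``source time + delay``.  For an
    inhibitory connection, target spikes falling within the suppression
    window after a source spike are deleted with the stated probability.
    Output trains are re-sorted and deduplicated at 0.1 ms resolution.
    """
    for c in connections:
        for eid in (c.source, c.target):
            if eid not in sts.layout.positions:
                raise KeyError(f"connection endpoint {eid!r} not in layout")

    rng = np.random.default_rng(seed)
    trains = {e: sts.spikes[e].copy() for e in sts.layout.electrodes}
    for c in connections:
        src = sts.spikes[c.source]          # propagate from original sources
        tgt = trains[c.target]
        delay = c.delay_ms / 1000.0
        if c.sign > 0:
            fire = src[rng.random(src.size) < c.probability] if c.probability < 1 else src
            inserted = fire + delay
            inserted = inserted[(inserted >= 0) & (inserted <= sts.duration)]
            tgt = np.concatenate([tgt, inserted])
        else:
            win = c.suppression_window_ms / 1000.0
            if tgt.size and src.size:
                idx = np.searchsorted(src, tgt, side="right") - 1
                has_prev = idx >= 0
                in_window = np.zeros(tgt.size, dtype=bool)
                in_window[has_prev] = (tgt[has_prev] - src[idx[has_prev]]) <= win
                doomed = in_window & (rng.random(tgt.size) < c.probability)
                tgt = tgt[~doomed]
        trains[c.target] = _dedup_sorted(np.sort(tgt))
    return SpikeTrainSet(sts.layout, trains, sts.duration)


def default_biphasic_template(sampling_rate: float = 10_000.0,
                              duration_ms: float = 1.4) -> np.ndarray:
    """A biphasic extracellular spike template (positive lobe, deep trough).

    Peak-to-peak amplitude is normalised to 1; the largest-magnitude sample
    (the trough) marks the spike time when the template is planted.
    """
    n = int(round(duration_ms / 1000.0 * sampling_rate))
    t = np.linspace(-1.0, 1.0, n)
    wave = 0.45 * np.exp(-((t + 0.45) / 0.28) ** 2) - np.exp(-(t / 0.22) ** 2)
    return wave / np.ptp(wave)


def synthesize_voltage(
    sts: SpikeTrainSet,
    template: np.ndarray | None = None,
    amplitude_sd_ratio: float = 10.0,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> VoltageRecording:
    """Render spike trains as voltage traces: template at each spike + noise.

    The template is scaled so its peak-to-peak amplitude equals
    ``amplitude_sd_ratio * noise_sd`` microvolts (or ``amplitude_sd_ratio``
    itself when ``noise_sd == 0``), aligned so its largest-magnitude sample
    sits at the spike time, and summed linearly where templates overlap.
    """
    fs = sts.layout.sampling_rate
    if template is None:
        template = default_biphasic_template(fs)
    template = np.asarray(template, dtype=float)
    if template.size >= 0.002 * fs:
        raise ValueError("template must be shorter than 2 ms")
    p2p = np.ptp(template)
    if p2p == 0:
        raise ValueError("template is flat")
    scale = amplitude_sd_ratio * (noise_sd if noise_sd > 0 else 1.0) / p2p
    tmpl = template * scale
    anchor = int(np.argmax(np.abs(tmpl)))

    n = int(round(sts.duration * fs))
    rng = np.random.default_rng(seed)
    traces: dict[str, np.ndarray] = {}
    min_gap = template.size / fs
    for e in sts.layout.electrodes:
        trace = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        times = sts.spikes[e]
        if times.size > 1 and np.min(np.diff(times)) < min_gap:
            warnings.warn(
                f"overlapping spike templates on electrode {e!r}; summed linearly")
        for t in times:
            i0 = int(round(t * fs)) - anchor
            lo, hi = max(i0, 0), min(i0 + tmpl.size, n)
            if hi > lo:
                trace[lo:hi] += tmpl[lo - i0:hi - i0]
        traces[e] = trace
    return VoltageRecording(sts.layout, traces, sts.duration)


def simulate_dose_response(
    ic50: float,
    hill_n: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Hill-equation inhibition curve with optional Gaussian noise, clipped at 0.

    response(c) = 1 / (1 + (c / ic50)**hill_n) + N(0, noise_sd)
    """
    if ic50 <= 0 or hill_n <= 0:
        raise ValueError("ic50 and hill_n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for c in concentrations:
        r = 1.0 / (1.0 + (c / ic50) ** hill_n)
        if noise_sd > 0:
            r += rng.normal(0.0, noise_sd)
        out.append((float(c), float(max(r, 0.0))))
    return out
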