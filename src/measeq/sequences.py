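"""Cluster activation sequences and their repetition statistics.

During each network burst, every cluster's instantaneous firing rate (IFR;
spike counts smoothed with a Gaussian kernel) rises to a peak.  The order in
which the clusters reach their IFR peaks is that burst's *activation
sequence*; the first cluster is the *initiator*.  Across a recording the
sequence list is summarised by run lengths (maximal series of identical
consecutive sequences), Shannon diversity H and equitability J of the
sequence-type frequencies, and a Monte Carlo permutation null that preserves
the observed type multiset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .bursts import NetworkBurst
from .io_core import SpikeTrainSet

__all__ = [
    "IfrTrace",
    "ActivationSequence",
    "SequenceStats",
    "compute_ifr",
    "extract_sequence",
    "extract_sequences",
    "run_lengths",
    "shannon_equitability",
    "monte_carlo_null",
    "compare_run_distributions",
    "sequence_stats",
]


@dataclass(frozen=True)
class IfrTrace:
    """Instantaneous firing rate on a uniform grid (spikes/s)."""

    times: np.ndarray
    rates: np.ndarray

    def integral(self) -> float:
        """Time integral of the rate, i.e. the implied spike count."""
        if self.times.size < 2:
            return 0.0
        dt = self.times[1] - self.times[0]
        return float(self.rates.sum() * dt)

    def peak_time(self) -> float:
        """Time of the global maximum; ties resolve to the earlier sample."""
        return float(self.times[int(np.argmax(self.rates))])


@dataclass(frozen=True)
class ActivationSequence:
    """Ordered cluster ids by IFR-peak time within one network burst."""

    order: tuple[int, ...]
    nb_start: float = 0.0

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("sequence elements must be distinct")
        if not self.order:
            raise ValueError("empty activation sequence")

    @property
    def initiator(self) -> int:
        return self.order[0]

    @property
    def participating(self) -> frozenset[int]:
        return frozenset(self.order)


def compute_ifr(spike_times: np.ndarray, t0: float, t1: float,
                kernel_sd_ms: float = 25.0, bin_ms: float = 1.0) -> IfrTrace:
    """Gaussian-kernel smoothed firing rate over [t0, t1].

    The kernel has SD ``kernel_sd_ms`` and is truncated at +-2 SD (so the
    default reproduces a 100 ms total smoothing window); it is normalised to
    unit area, which makes the trace linear in the input and its integral
    equal to the spike count (up to truncation and edge effects).
    """
    if kernel_sd_ms <= 0:
        raise ValueError("kernel SD must be positive")
    if bin_ms > kernel_sd_ms / 5:
        raise ValueError("bin must be at most kernel_sd / 5 for faithful smoothing")
    bin_s = bin_ms / 1000.0
    sd_s = kernel_sd_ms / 1000.0
    edges = np.arange(t0, t1 + bin_s, bin_s)
    centres = (edges[:-1] + edges[1:]) / 2
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= t0) & (t <= t1)]
    counts, _ = np.histogram(t, bins=edges)

    half = int(np.ceil(2 * sd_s / bin_s))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * bin_s) / sd_s) ** 2)
    k /= k.sum()
    rates = np.convolve(counts, k, mode="same") / bin_s
    return IfrTrace(centres, rates)


def extract_sequence(nb: NetworkBurst, sts: SpikeTrainSet,
                     kernel_sd_ms: float = 25.0, bin_ms: float = 1.0) -> ActivationSequence:
    """Order the clusters of one NB by the time of their IFR peak.

    The IFR is evaluated over the NB span padded by 2 kernel SDs.  Clusters
    with no spikes in the NB are excluded (partial sequence); peak-time ties
    resolve to the earlier sample, then to the lower cluster id.
    """
    pad = 2 * kernel_sd_ms / 1000.0
    t0, t1 = nb.start - pad, nb.end + pad
    entries: list[tuple[float, int]] = []
    for cid in sts.layout.cluster_ids:
        spikes = nb.cluster_spikes.get(cid)
        if spikes is None:
            spikes = sts.cluster_spikes(cid, nb.start, nb.end)
        if spikes.size == 0:
            continue
        window = sts.cluster_spikes(cid, t0, t1)
        ifr = compute_ifr(window, t0, t1, kernel_sd_ms, bin_ms)
        entries.append((ifr.peak_time(), cid))
    if not entries:
        raise ValueError("network burst with all clusters silent")
    entries.sort()
    return ActivationSequence(tuple(cid for _, cid in entries), nb.start)


def extract_sequences(nbs: Sequence[NetworkBurst], sts: SpikeTrainSet,
                      kernel_sd_ms: float = 25.0, bin_ms: float = 1.0,
                      full_only: bool = False) -> list[ActivationSequence]:
    """Per-NB activation sequences, in NB time order.

    ``full_only`` restricts the list to sequences in which every cluster of
    the layout participates.
    """
    n_clusters = len(sts.layout.cluster_ids)
    seqs = [extract_sequence(nb, sts, kernel_sd_ms, bin_ms)
            for nb in sorted(nbs, key=lambda nb: nb.start)]
    if full_only:
        seqs = [s for s in seqs if len(s.order) == n_clusters]
    return seqs


def _orders(sequences: Sequence) -> list[tuple[int, ...]]:
    return [s.order if isinstance(s, ActivationSequence) else tuple(s)
            for s in sequences]


def run_lengths(sequences: Sequence) -> list[int]:
    """Lengths of maximal runs of identical consecutive sequences.

    Equality is exact: the same ordered tuple, including which clusters
    participate.  Singleton runs (length 1) are included; "repeated"
    sequences are the runs of length >= 2.
    """
    orders = _orders(sequences)
    if not orders:
        return []
    out = []
    cur = 1
    for prev, nxt in zip(orders, orders[1:]):
        if nxt == prev:
            cur += 1
        else:
            out.append(cur)
            cur = 1
    out.append(cur)
    return out


def shannon_equitability(counts: Sequence[int] | Counter) -> tuple[float, float]:
    """Shannon diversity H (nats) and equitability J of type counts.

    H = -sum p_i ln p_i over the observed (positive-count) types;
    J = H / ln(N) with N the number of observed types, and J = 0 when N = 1.
    """
    if isinstance(counts, Counter):
        counts = list(counts.values())
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if c.size == 0:
        raise ValueError("all counts are zero")
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    j = 0.0 if c.size == 1 else h / np.log(c.size)
    return h, j


def monte_carlo_null(sequences: Sequence, n_iter: int = 1000,
                     seed: int = 0) -> dict:
    """Permutation null of the run-length distribution.

    Each iteration uniformly permutes the observed sequence list (preserving
    the multiset of types exactly) and records the resulting run lengths.
    Returns the pooled lengths plus per-iteration mean and max summaries.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    orders = _orders(sequences)
    if len(orders) < 2:
        raise ValueError("need at least 2 sequences for a permutation null")
    rng = np.random.default_rng(seed)
    # map to integer labels once; permutation happens on labels
    labels = {}
    coded = np.array([labels.setdefault(o, len(labels)) for o in orders])
    pooled: list[int] = []
    means = np.empty(n_iter)
    maxes = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        perm = coded[rng.permutation(coded.size)]
        change = np.nonzero(np.diff(perm))[0]
        bounds = np.concatenate([[-1], change, [perm.size - 1]])
        lens = np.diff(bounds)
        pooled.extend(int(x) for x in lens)
        means[i] = lens.mean()
        maxes[i] = lens.max()
    return {
        "pooled_run_lengths": pooled,
        "iteration_mean": means,
        "iteration_max": maxes,
        "n_iter": n_iter,
        "seed": seed,
    }


def compare_run_distributions(observed: Sequence[int],
                              reference: Sequence[int]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of run-length samples."""
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.size == 0 or ref.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(obs, ref, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SequenceStats:
    """Full repetition summary of a recording's activation-sequence list."""

    type_counts: Counter
    runs: list[int]
    repeated_runs: list[int]                 # runs of length >= 2
    shannon_h: float
    equitability_j: float
    null: dict = field(default_factory=dict)
    ks_d_vs_null: float | None = None
    ks_p_vs_null: float | None = None

    @property
    def n_sequences(self) -> int:
        return sum(self.type_counts.values())


def sequence_stats(sequences: Sequence, n_iter: int = 1000, seed: int = 0,
                   include_singleton_runs: bool = True) -> SequenceStats:
    """Run lengths, diversity, and the Monte Carlo null, in one pass.

    ``include_singleton_runs`` controls which runs enter the observed-vs-null
    KS comparison (cumulative-frequency plots conventionally use runs of
    length >= 2; internal statistics use all runs).
    """
    orders = _orders(sequences)
    counts = Counter(orders)
    runs = run_lengths(orders)
    repeated = [r for r in runs if r >= 2]
    h, j = shannon_equitability(counts)
    null = monte_carlo_null(orders, n_iter=n_iter, seed=seed) if len(orders) >= 2 else {}
    d = p = None
    if null:
        obs = runs if include_singleton_runs else repeated
        ref = (null["pooled_run_lengths"] if include_singleton_runs
               else [r for r in null["pooled_run_lengths"] if r >= 2])
        if obs and ref:
            d, p = compare_run_distributions(obs, ref)
    return SequenceStats(counts, runs, repeated, h, j, null, d, p)
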