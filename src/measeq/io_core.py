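"""Domain types, layouts, configuration, and spike-train file I/O.

The central currency of the package is the :class:`SpikeTrainSet`: per-electrode
sorted spike times (seconds) together with the electrode layout that maps each
electrode to one of four spatial clusters (quadrants) of the MEA.

Time base is seconds as floats everywhere inside the package; sample indices
("ticks") appear only at I/O boundaries (the MAT dialect stores ticks at the
recording sampling rate).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Layout",
    "SpikeTrainSet",
    "VoltageRecording",
    "RunConfig",
    "DetectionConfig",
    "BurstConfig",
    "SequenceConfig",
    "ConnectivityConfig",
    "DoseResponseConfig",
    "LayoutMismatchError",
    "SpikeTrainValidationError",
    "default_layout_4q",
    "read_layout",
    "write_layout",
    "read_spike_trains",
    "write_spike_trains",
    "read_voltage",
    "write_voltage",
]


class LayoutMismatchError(ValueError):
    """An electrode id in the data cannot be resolved against the layout."""


class SpikeTrainValidationError(ValueError):
    """A spike train violates ordering or range invariants."""


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Layout:
    """Electrode layout of a clustered MEA.

    Parameters
    ----------
    electrodes
        Ordered electrode ids (strings).
    positions
        Mapping electrode id -> (x, y) in micrometres, origin at array centre.
    clusters
        Mapping electrode id -> cluster id in {1, 2, 3, 4}.
    sampling_rate
        Acquisition sampling rate in Hz (default 10 kHz).
    """

    electrodes: tuple[str, ...]
    positions: Mapping[str, tuple[float, float]]
    clusters: Mapping[str, int]
    sampling_rate: float = 10_000.0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(set(self.electrodes)) != len(self.electrodes):
            raise ValueError("electrode ids must be unique")
        for e in self.electrodes:
            if e not in self.positions or e not in self.clusters:
                raise ValueError(f"electrode {e!r} missing position or cluster")
        pos = [tuple(self.positions[e]) for e in self.electrodes]
        if len(set(pos)) != len(pos):
            raise ValueError("electrode positions must be unique")
        present = set(self.clusters[e] for e in self.electrodes)
        if not present:
            raise ValueError("empty layout")
        if any(not isinstance(c, (int, np.integer)) or c < 1 for c in present):
            raise ValueError("cluster ids must be positive integers")

    @property
    def cluster_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.clusters[e] for e in self.electrodes)))

    def cluster_members(self, cluster_id: int) -> tuple[str, ...]:
        return tuple(e for e in self.electrodes if self.clusters[e] == cluster_id)

    def distance_um(self, a: str, b: str) -> float:
        xa, ya = self.positions[a]
        xb, yb = self.positions[b]
        return float(np.hypot(xa - xb, ya - yb))


def default_layout_4q(
    pitch_um: float = 200.0,
    quadrant_offset_um: float = 1000.0,
    sampling_rate: float = 10_000.0,
) -> Layout:
    """The default 60-electrode, four-quadrant layout (15 electrodes/quadrant).

    Each quadrant is a 4x4 grid with the outer corner removed, centred at
    (+-quadrant_offset, +-quadrant_offset).  Coordinates are a documented
    convention: micrometres, origin at the array centre.  Quadrant numbering
    is counter-clockwise from the upper-right.
    """
    quadrant_signs = {1: (1, 1), 2: (-1, 1), 3: (-1, -1), 4: (1, -1)}
    electrodes: list[str] = []
    positions: dict[str, tuple[float, float]] = {}
    clusters: dict[str, int] = {}
    grid = [(i, j) for i in range(4) for j in range(4)]
    for q, (sx, sy) in quadrant_signs.items():
        # drop the corner farthest from the centre -> 15 electrodes
        cells = [c for c in grid if c != (3, 3)]
        for k, (i, j) in enumerate(cells):
            eid = f"q{q}e{k + 1:02d}"
            x = sx * (quadrant_offset_um - 1.5 * pitch_um + i * pitch_um)
            y = sy * (quadrant_offset_um - 1.5 * pitch_um + j * pitch_um)
            electrodes.append(eid)
            positions[eid] = (x, y)
            clusters[eid] = q
    return Layout(tuple(electrodes), positions, clusters, sampling_rate)


def write_layout(layout: Layout, path: str | Path) -> None:
    """Write a layout as CSV (electrode_id, x_um, y_um, cluster_id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["electrode_id", "x_um", "y_um", "cluster_id"])
        for e in layout.electrodes:
            x, y = layout.positions[e]
            w.writerow([e, repr(x), repr(y), layout.clusters[e]])


def read_layout(path: str | Path, sampling_rate: float = 10_000.0) -> Layout:
    """Read a CSV layout file (electrode_id, x_um, y_um, cluster_id)."""
    electrodes, positions, clusters = [], {}, {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            e = row["electrode_id"]
            electrodes.append(e)
            positions[e] = (float(row["x_um"]), float(row["y_um"]))
            clusters[e] = int(row["cluster_id"])
    return Layout(tuple(electrodes), positions, clusters, sampling_rate)


# ---------------------------------------------------------------------------
# Spike trains and voltage
# ---------------------------------------------------------------------------

def _validated_train(eid: str, times: Iterable[float], duration: float) -> np.ndarray:
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                   dtype=float).ravel()
    if t.size and (np.any(np.diff(t) <= 0)):
        raise SpikeTrainValidationError(
            f"spike times on electrode {eid!r} are not strictly increasing")
    if t.size and (t[0] < 0 or t[-1] > duration):
        raise SpikeTrainValidationError(
            f"spike times on electrode {eid!r} fall outside [0, {duration}] s")
    return t


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-electrode sorted spike times (seconds) plus the electrode layout."""

    layout: Layout
    spikes: Mapping[str, np.ndarray]
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        validated = {}
        for eid in self.layout.electrodes:
            validated[eid] = _validated_train(eid, self.spikes.get(eid, ()), self.duration)
        for eid in self.spikes:
            if eid not in self.layout.positions:
                raise LayoutMismatchError(f"unknown electrode id {eid!r}")
        object.__setattr__(self, "spikes", validated)

    def train(self, eid: str) -> np.ndarray:
        return self.spikes[eid]

    def counts(self) -> dict[str, int]:
        return {e: int(self.spikes[e].size) for e in self.layout.electrodes}

    def total_spikes(self) -> int:
        return int(sum(v.size for v in self.spikes.values()))

    def cluster_spikes(self, cluster_id: int,
                       t0: float | None = None, t1: float | None = None) -> np.ndarray:
        """Pooled sorted spike times of one cluster, optionally windowed."""
        parts = [self.spikes[e] for e in self.layout.cluster_members(cluster_id)]
        pooled = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        if t0 is not None or t1 is not None:
            lo = t0 if t0 is not None else -np.inf
            hi = t1 if t1 is not None else np.inf
            pooled = pooled[(pooled >= lo) & (pooled <= hi)]
        return pooled

    def equal_within(self, other: "SpikeTrainSet", tol: float = 0.0) -> bool:
        if self.layout.electrodes != other.layout.electrodes:
            return False
        if abs(self.duration - other.duration) > max(tol, 0):
            return False
        for e in self.layout.electrodes:
            a, b = self.spikes[e], other.spikes[e]
            if a.size != b.size:
                return False
            if a.size and np.max(np.abs(a - b)) > tol:
                return False
        return True


@dataclass(frozen=True)
class VoltageRecording:
    """Raw extracellular voltage (microvolts) per electrode at uniform rate."""

    layout: Layout
    samples: Mapping[str, np.ndarray]
    duration: float

    def __post_init__(self):
        n = None
        for eid in self.layout.electrodes:
            s = np.asarray(self.samples[eid], dtype=float)
            if n is None:
                n = s.size
            elif s.size != n:
                raise ValueError("all electrodes must have equal trace length")
        expected = self.duration * self.layout.sampling_rate
        if n is not None and abs(n - expected) > 1:
            raise ValueError(
                f"trace length {n} inconsistent with duration {self.duration}s "
                f"at {self.layout.sampling_rate} Hz")

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.samples[self.layout.electrodes[0]]).size)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.layout.sampling_rate


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DetectionConfig:
    threshold_factor: float = 8.0        # multiple of noise SD (peak-to-peak)
    peak_lifetime_ms: float = 2.0        # max separation of the extremum pair
    refractory_ms: float = 1.0
    noise_window_s: float | None = None  # None -> whole-trace MAD estimate


@dataclass
class BurstConfig:
    min_spikes: int = 5
    max_isi_s: float = 0.1
    nb_min_fraction: float = 0.20
    nb_merge_s: float = 0.1
    active_mfr_threshold: float = 0.1    # spikes/s, strict inequality
    participation_base: str = "active"   # "active" or "all"


@dataclass
class SequenceConfig:
    kernel_window_ms: float = 100.0      # total Gaussian window (support)
    kernel_sd_ms: float = 25.0           # window = +-2 sd
    bin_ms: float = 1.0
    mc_iterations: int = 1000
    include_singleton_runs: bool = True
    full_sequences_only: bool = False


@dataclass
class ConnectivityConfig:
    bin_ms: float = 1.0
    max_delay_ms: float = 25.0
    averaging_windows: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    edge_windows: tuple[int, ...] = (2, 3)
    crossing_windows: tuple[int, ...] = (0,)
    min_spikes_per_train: int = 10
    speed_bounds_m_s: tuple[float, float] = (0.02, 2.0)
    latency_bounds_ms: tuple[float, float] = (1.0, 25.0)
    n_surrogates: int = 100
    surrogate_jitter_ms: float = 10.0
    surrogate_percentile: float = 99.0
    ci0_sync_halfwidth_ms: float = 1.0
    ci0_lag_halfwidth_ms: float = 100.0
    ci0_bin_ms: float = 0.5


@dataclass
class DoseResponseConfig:
    fixed_top: float | None = 1.0
    fixed_bottom: float | None = 0.0
    highlighted_concentration_m: float = 2e-9  # working concentration of MK-801


@dataclass
class RunConfig:
    """All tunable parameters of every stage, defaulting to the study settings."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bursts: BurstConfig = field(default_factory=BurstConfig)
    sequences: SequenceConfig = field(default_factory=SequenceConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    dose_response: DoseResponseConfig = field(default_factory=DoseResponseConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        def build(factory, section):
            base = factory()
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(base, k):
                    raise ValueError(f"unknown config key {section}.{k}")
                if isinstance(getattr(base, k), tuple) and v is not None:
                    v = tuple(v)
                setattr(base, k, v)
            return base

        return cls(
            detection=build(DetectionConfig, "detection"),
            bursts=build(BurstConfig, "bursts"),
            sequences=build(SequenceConfig, "sequences"),
            connectivity=build(ConnectivityConfig, "connectivity"),
            dose_response=build(DoseResponseConfig, "dose_response"),
            seed=int(raw.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# Spike-train file I/O
# ---------------------------------------------------------------------------

def write_spike_trains(sts: SpikeTrainSet, path: str | Path, format: str = "csv") -> None:
    """Write a SpikeTrainSet to disk.

    Formats: ``csv`` (long form: electrode_id, spike_time_s) and ``hdf5``
    (one variable-length dataset per electrode under /spikes, duration and
    sampling rate as root attributes).  Electrodes with no spikes are
    represented implicitly (csv) or as empty datasets (hdf5); both formats
    round-trip bit-exactly.
    """
    path = Path(path)
    try:
        if format == "csv":
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["electrode_id", "spike_time_s"])
                for e in sts.layout.electrodes:
                    for t in sts.spikes[e]:
                        w.writerow([e, repr(float(t))])
        elif format == "hdf5":
            import h5py
            with h5py.File(path, "w") as f:
                f.attrs["duration_s"] = sts.duration
                f.attrs["sampling_rate_hz"] = sts.layout.sampling_rate
                g = f.create_group("spikes")
                for e in sts.layout.electrodes:
                    g.create_dataset(e, data=sts.spikes[e], dtype="f8")
        else:
            raise ValueError(f"unsupported write format {format!r}")
    except OSError as err:
        raise OSError(f"failed writing spike trains to {path}: {err}") from err


def read_spike_trains(path: str | Path, format: str, layout: Layout,
                      duration: float | None = None) -> SpikeTrainSet:
    """Read spike trains from ``csv``, ``hdf5`` or the read-only ``mat`` dialect.

    The MAT dialect expects a cell array with one cell per layout electrode
    (layout order), each holding spike times as sample ticks at the layout
    sampling rate; ticks are converted to seconds on load.  Any structural
    mismatch raises rather than guessing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    known = set(layout.electrodes)

    if format == "csv":
        trains: dict[str, list[float]] = {e: [] for e in layout.electrodes}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                e = row["electrode_id"]
                if e not in known:
                    raise LayoutMismatchError(f"unknown electrode id {e!r} in {path}")
                trains[e].append(float(row["spike_time_s"]))
        if duration is None:
            mx = max((ts[-1] for ts in trains.values() if ts), default=0.0)
            duration = mx if mx > 0 else 1.0
        return SpikeTrainSet(layout, {e: np.asarray(v) for e, v in trains.items()}, duration)

    if format == "hdf5":
        import h5py
        with h5py.File(path, "r") as f:
            dur = float(f.attrs["duration_s"]) if duration is None else duration
            trains = {}
            for e in f["spikes"]:
                if e not in known:
                    raise LayoutMismatchError(f"unknown electrode id {e!r} in {path}")
                trains[e] = np.asarray(f["spikes"][e], dtype=float)
        return SpikeTrainSet(layout, trains, dur)

    if format == "mat":
        from scipy.io import loadmat
        raw = loadmat(path, squeeze_me=False)
        cell_vars = {k: v for k, v in raw.items()
                     if not k.startswith("__") and isinstance(v, np.ndarray)
                     and v.dtype == object}
        if len(cell_vars) != 1:
            raise ValueError(
                f"expected exactly one cell-array variable in {path}, "
                f"found {sorted(cell_vars)}")
        (name, cells), = cell_vars.items()
        cells = cells.ravel()
        if cells.size != len(layout.electrodes):
            raise LayoutMismatchError(
                f"cell array {name!r} has {cells.size} entries, layout has "
                f"{len(layout.electrodes)} electrodes")
        fs = layout.sampling_rate
        trains = {}
        for e, cell in zip(layout.electrodes, cells):
            ticks = np.asarray(cell, dtype=float).ravel()
            trains[e] = ticks / fs
        if duration is None:
            mx = max((t[-1] for t in trains.values() if t.size), default=0.0)
            duration = mx if mx > 0 else 1.0
        return SpikeTrainSet(layout, trains, duration)

    raise ValueError(f"unsupported read format {format!r}")


def write_voltage(rec: VoltageRecording, path: str | Path) -> None:
    """Write a voltage recording as HDF5 (one float dataset per electrode)."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = rec.duration
        f.attrs["sampling_rate_hz"] = rec.layout.sampling_rate
        g = f.create_group("voltage")
        for e in rec.layout.electrodes:
            g.create_dataset(e, data=np.asarray(rec.samples[e], dtype=float))


def read_voltage(path: str | Path, layout: Layout) -> VoltageRecording:
    """Read an HDF5 voltage recording against a known layout."""
    import h5py
    with h5py.File(path, "r") as f:
        dur = float(f.attrs["duration_s"])
        samples = {}
        for e in f["voltage"]:
            if e not in layout.positions:
                raise LayoutMismatchError(f"unknown electrode id {e!r} in {path}")
            samples[e] = np.asarray(f["voltage"][e], dtype=float)
    return VoltageRecording(layout, samples, dur)
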