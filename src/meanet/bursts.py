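"""Single-channel spike bursts and population network bursts.

Spike bursts use the max-interval convention: a burst is a maximal run of
consecutive spikes on one electrode whose every inter-spike interval is at
most ``max_isi`` (default 100 ms) with at least ``min_spikes`` spikes
(default 5).

Network bursts use a population-rate threshold: total spikes are binned
(default 25 ms); bins whose count exceeds mean + k x sd of the binned rate
(default k=3) are candidates; candidates closer than ``merge_gap``
(default 100 ms) merge into one event, and events are kept only when the
number of distinct participating electrodes reaches ``min_participation``
(default 10%) of the active electrodes.  An electrode is *active* when its
rate is at least 0.02 spikes/s over the recording (6 spikes in 5 min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import DistributionSummary, summarize
from .core import SpikeRaster
from .errors import InvalidArgumentError

__all__ = [
    "Burst",
    "NetworkBurst",
    "BurstStats",
    "detect_bursts",
    "detect_all_bursts",
    "detect_network_bursts",
    "burst_stats",
    "network_burst_stats",
    "active_electrodes",
    "ACTIVE_RATE_THRESHOLD",
]

#: spikes/s above which an electrode counts as active
ACTIVE_RATE_THRESHOLD = 0.02


@dataclass(frozen=True)
class Burst:
    """A single-electrode spike burst (start/end are spike times, s)."""

    electrode_id: int
    start: float
    end: float
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass(frozen=True)
class NetworkBurst:
    """A population-wide burst event."""

    start: float
    end: float
    participating_electrodes: frozenset
    peak_population_rate: float      # spikes/s across the array at the peak bin

    @property
    def n_participants(self) -> int:
        return len(self.participating_electrodes)

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass
class BurstStats:
    count: int
    frequency_per_min: float
    mean_duration_ms: float          # nan when count == 0
    duration_summary: DistributionSummary | None


def detect_bursts(spiketrain, max_isi_ms: float = 100.0, min_spikes: int = 5,
                  electrode_id: int = 0) -> list[Burst]:
    """Maximal runs of spikes with every ISI <= ``max_isi_ms``."""
    if max_isi_ms <= 0:
        raise InvalidArgumentError("max_isi must be positive")
    if min_spikes < 2:
        raise InvalidArgumentError("min_spikes must be >= 2")
    t = np.asarray(spiketrain, dtype=float)
    if t.size < min_spikes:
        return []
    close = np.diff(t) <= max_isi_ms / 1000.0
    bursts = []
    run_start = None
    for i, c in enumerate(close):
        if c and run_start is None:
            run_start = i
        if (not c or i == close.size - 1) and run_start is not None:
            run_end = i + 1 if c else i           # index of last spike in run
            n = run_end - run_start + 1
            if n >= min_spikes:
                bursts.append(Burst(electrode_id=electrode_id,
                                    start=float(t[run_start]),
                                    end=float(t[run_end]), n_spikes=n))
            run_start = None
    return bursts


def detect_all_bursts(raster: SpikeRaster, max_isi_ms: float = 100.0,
                      min_spikes: int = 5) -> list[Burst]:
    out = []
    for i, t in enumerate(raster.spikes):
        out.extend(detect_bursts(t, max_isi_ms, min_spikes, electrode_id=i))
    return out


def active_electrodes(raster: SpikeRaster,
                      min_rate: float = ACTIVE_RATE_THRESHOLD) -> np.ndarray:
    """Ids of electrodes whose overall rate reaches ``min_rate``."""
    rates = raster.spike_counts() / raster.duration_s
    return np.flatnonzero(rates >= min_rate)


def detect_network_bursts(raster: SpikeRaster, bin_ms: float = 25.0,
                          k: float = 3.0, merge_gap_ms: float = 100.0,
                          min_participation: float = 0.1) -> list[NetworkBurst]:
    """Population-rate-threshold network-burst detector."""
    if bin_ms <= 0:
        raise InvalidArgumentError("bin must be positive")
    if not (0.0 < min_participation <= 1.0):
        raise InvalidArgumentError("min_participation must be in (0, 1]")
    times, ids = raster.events()
    if times.size == 0:
        return []
    bin_s = bin_ms / 1000.0
    n_bins = max(1, int(np.ceil(raster.duration_s / bin_s)))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(times, bins=edges)
    thr = counts.mean() + k * counts.std()
    candidates = np.flatnonzero(counts > thr)
    if candidates.size == 0:
        return []
    active = active_electrodes(raster)
    min_count = max(1, int(np.ceil(min_participation * active.size)))
    gap_bins = int(np.floor(merge_gap_ms / bin_ms))
    # group candidate bins whose separation is within the merge gap
    groups = np.split(candidates, np.flatnonzero(np.diff(candidates) > gap_bins + 1) + 1)
    bin_of = np.minimum((times / bin_s).astype(int), n_bins - 1)
    events = []
    for grp in groups:
        start, end = edges[grp[0]], edges[grp[-1] + 1]
        # participants are electrodes spiking in the supra-threshold bins;
        # spikes inside sub-threshold gaps of a merged event do not count
        sel = np.isin(bin_of, grp)
        participants = frozenset(np.unique(ids[sel]).tolist())
        if len(participants) < min_count:
            continue
        peak = counts[grp].max() / bin_s
        events.append(NetworkBurst(start=float(start), end=float(end),
                                   participating_electrodes=participants,
                                   peak_population_rate=float(peak)))
    return events


def _stats(durations_ms: np.ndarray, count: int, duration_s: float) -> BurstStats:
    if duration_s <= 0:
        raise InvalidArgumentError("recording duration must be positive")
    freq = count / (duration_s / 60.0)
    if count == 0:
        return BurstStats(count=0, frequency_per_min=0.0,
                          mean_duration_ms=float("nan"), duration_summary=None)
    return BurstStats(count=count, frequency_per_min=freq,
                      mean_duration_ms=float(durations_ms.mean()),
                      duration_summary=summarize(durations_ms))


def burst_stats(bursts: list[Burst], recording_duration_s: float) -> BurstStats:
    d = np.array([b.duration_ms for b in bursts])
    return _stats(d, len(bursts), recording_duration_s)


def network_burst_stats(events: list[NetworkBurst],
                        recording_duration_s: float) -> BurstStats:
    d = np.array([e.duration_ms for e in events])
    return _stats(d, len(events), recording_duration_s)
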