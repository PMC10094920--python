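"""Center-of-activity trajectory (CAT) analysis.

The center of activity (CA) of a time bin is the spike-count-weighted
centroid of electrode positions,

    CA(t) = sum_i n_i(t) p_i / sum_i n_i(t),

with positions p_i in mm relative to the arena centre.  Homogeneous
population activity puts the CA at the origin; localized activity pulls
it toward the active region.  Tracing the CA across the bins of one
network burst gives the CAT, summarised by its duration, mean velocity
(path length over duration), terminal distance from the arena centre and
dispersion (RMS distance of points from their own centroid).

Empty bins are flagged, never interpolated: interpolation would fabricate
motion that the spikes do not show.  The default 10 ms bin is applied
inside network-burst windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import DistributionSummary, summarize
from .bursts import NetworkBurst
from .core import SpikeRaster
from .errors import InvalidArgumentError, NoDataError

__all__ = ["CAPoint", "CATrajectory", "center_of_activity", "compute_cat",
           "cat_summary"]


@dataclass(frozen=True)
class CAPoint:
    """Center of activity of one time bin (position undefined if silent)."""

    t: float                    # bin centre, s
    x: float
    y: float
    total_activity: int         # spikes in the bin

    @property
    def defined(self) -> bool:
        return self.total_activity > 0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


def center_of_activity(raster: SpikeRaster, window: tuple[float, float],
                       bin_ms: float = 10.0) -> list[CAPoint]:
    """CA points across a time window; silent bins flagged undefined."""
    start, end = window
    if bin_ms <= 0:
        raise InvalidArgumentError("bin must be positive")
    if start < 0 or end > raster.duration_s or end <= start:
        raise InvalidArgumentError(
            f"window ({start}, {end}) outside recording [0, {raster.duration_s}]")
    bin_s = bin_ms / 1000.0
    n_bins = max(1, int(np.ceil((end - start) / bin_s)))
    edges = start + np.arange(n_bins + 1) * bin_s
    times, ids = raster.events()
    sel = (times >= start) & (times < end)
    times, ids = times[sel], ids[sel]
    which = np.minimum(np.floor((times - start) / bin_s).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    px = raster.layout.positions[ids, 0]
    py = raster.layout.positions[ids, 1]
    sx = np.bincount(which, weights=px, minlength=n_bins)
    sy = np.bincount(which, weights=py, minlength=n_bins)
    points = []
    for b in range(n_bins):
        t_mid = float((edges[b] + edges[b + 1]) / 2.0)
        n = int(counts[b])
        if n == 0:
            points.append(CAPoint(t=t_mid, x=float("nan"), y=float("nan"),
                                  total_activity=0))
        else:
            points.append(CAPoint(t=t_mid, x=float(sx[b] / n), y=float(sy[b] / n),
                                  total_activity=n))
    return points


@dataclass
class CATrajectory:
    """Time-ordered CA points of one network burst with motion summaries."""

    burst_id: int
    points: list[CAPoint] = field(repr=False)
    duration_ms: float = 0.0
    path_length_mm: float = 0.0
    mean_velocity_mm_s: float = 0.0
    terminal_distance_mm: float = float("nan")
    dispersion_mm: float = float("nan")
    degenerate: bool = True

    @property
    def defined_points(self) -> list[CAPoint]:
        return [p for p in self.points if p.defined]


def compute_cat(raster: SpikeRaster, network_burst: NetworkBurst | tuple,
                bin_ms: float = 10.0, burst_id: int = 0) -> CATrajectory:
    """CAT of one network burst.

    Velocity is the total path length over the trajectory duration
    (time between the first and last defined CA point); skipped silent
    bins therefore contribute their real time gap, not fabricated motion.
    Fewer than two defined points makes the trajectory degenerate.
    """
    if isinstance(network_burst, NetworkBurst):
        window = (network_burst.start, network_burst.end)
    else:
        window = tuple(network_burst)
    points = center_of_activity(raster, window, bin_ms)
    traj = CATrajectory(burst_id=burst_id, points=points)
    defined = traj.defined_points
    if not defined:
        return traj
    xy = np.array([[p.x, p.y] for p in defined])
    centroid = xy.mean(axis=0)
    traj.dispersion_mm = float(np.sqrt(((xy - centroid) ** 2).sum(axis=1).mean()))
    traj.terminal_distance_mm = float(np.linalg.norm(xy[-1]))
    if len(defined) < 2:
        return traj
    traj.degenerate = False
    traj.duration_ms = (defined[-1].t - defined[0].t) * 1000.0
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    traj.path_length_mm = float(steps.sum())
    if traj.duration_ms > 0:
        traj.mean_velocity_mm_s = traj.path_length_mm / (traj.duration_ms / 1000.0)
    return traj


def cat_summary(trajectories: list[CATrajectory]) -> dict[str, DistributionSummary]:
    """Condition-level summaries over non-degenerate trajectories."""
    valid = [t for t in trajectories if not t.degenerate]
    if not valid:
        raise NoDataError("all trajectories are degenerate")
    return {
        "velocity_mm_s": summarize([t.mean_velocity_mm_s for t in valid]),
        "duration_ms": summarize([t.duration_ms for t in valid]),
        "terminal_distance_mm": summarize([t.terminal_distance_mm for t in valid]),
        "dispersion_mm": summarize([t.dispersion_mm for t in valid]),
    }
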