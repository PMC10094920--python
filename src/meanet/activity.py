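"""Firing-rate maps, interspike-interval statistics and group comparisons.

Mean firing rate (MFR) is spikes per second per electrode over the whole
recording.  Interspike intervals (ISI) are successive-spike differences
within each electrode, reported in milliseconds; by default they are pooled
across electrodes, matching a single per-culture ISI distribution.
Group comparisons use the unpaired two-tailed Welch t-test, with the
significance tiers * p<0.05, ** p<0.01, *** p<0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpikeRaster
from .errors import DegenerateInputError, InvalidArgumentError, NoDataError

__all__ = [
    "ActivityMap",
    "DistributionSummary",
    "WelchResult",
    "mean_firing_rate",
    "interspike_intervals",
    "average_isi_ratio",
    "summarize",
    "welch_t_test",
    "significance_tier",
]

#: display ceiling of activity maps, spikes/s
MFR_DISPLAY_CEILING = 10.0


@dataclass
class ActivityMap:
    """Per-electrode mean firing rate for one recording."""

    rates: np.ndarray           # spikes/s per electrode
    duration_s: float
    display_ceiling: float = MFR_DISPLAY_CEILING

    @property
    def mean(self) -> float:
        return float(self.rates.mean())

    def clipped(self) -> np.ndarray:
        """Rates clipped to the display ceiling (for plotting only)."""
        return np.minimum(self.rates, self.display_ceiling)


def mean_firing_rate(raster: SpikeRaster) -> ActivityMap:
    """MFR_i = spike count / duration for every electrode (zeros kept)."""
    if raster.duration_s <= 0:
        raise InvalidArgumentError("duration must be positive")
    rates = raster.spike_counts() / raster.duration_s
    return ActivityMap(rates=rates, duration_s=raster.duration_s)


def interspike_intervals(raster: SpikeRaster, pooling: str = "pooled"):
    """Successive-spike intervals in ms.

    ``pooled`` concatenates ISIs across electrodes into one array;
    ``per_electrode`` returns a list of arrays, one per electrode
    (empty for electrodes with fewer than two spikes).
    """
    if pooling not in ("pooled", "per_electrode"):
        raise InvalidArgumentError(f"unknown pooling {pooling!r}")
    per = [np.diff(t) * 1000.0 for t in raster.spikes]
    if pooling == "per_electrode":
        return per
    non_empty = [d for d in per if d.size]
    if not non_empty:
        return np.empty(0)
    return np.concatenate(non_empty)


def average_isi_ratio(raster_a: SpikeRaster, raster_b: SpikeRaster,
                      pooling: str = "pooled") -> float:
    """100 x mean ISI of ``raster_b`` over mean ISI of ``raster_a``.

    Used to express how far the average ISI has dropped between two
    recording ages: a value of 35.7 means the later culture's mean ISI is
    35.7% of the earlier one's.
    """
    isi_a = interspike_intervals(raster_a, pooling="pooled")
    isi_b = interspike_intervals(raster_b, pooling="pooled")
    if pooling == "per_electrode":
        per_a = [d.mean() for d in interspike_intervals(raster_a, "per_electrode") if d.size]
        per_b = [d.mean() for d in interspike_intervals(raster_b, "per_electrode") if d.size]
        if not per_a or not per_b:
            raise NoDataError("need at least one ISI in each raster")
        return 100.0 * float(np.mean(per_b)) / float(np.mean(per_a))
    if isi_a.size == 0 or isi_b.size == 0:
        raise NoDataError("need at least one ISI in each raster")
    return 100.0 * float(isi_b.mean()) / float(isi_a.mean())


@dataclass
class DistributionSummary:
    """Box/violin-style summary of one sample.

    Quartiles use linear interpolation between order statistics; whiskers
    follow the 1.5 x interquartile-range rule; SEM uses the n-1 standard
    deviation.
    """

    median: float
    lower_quartile: float
    upper_quartile: float
    whisker_low: float
    whisker_high: float
    mean: float
    sem: float
    n: int


def summarize(values) -> DistributionSummary:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise NoDataError("cannot summarize an empty sample")
    if np.all(x == x[0]):       # constant sample: exact, no rounding residue
        v = float(x[0])
        return DistributionSummary(median=v, lower_quartile=v, upper_quartile=v,
                                   whisker_low=v, whisker_high=v, mean=v,
                                   sem=0.0, n=int(x.size))
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    return DistributionSummary(
        median=float(med), lower_quartile=float(q1), upper_quartile=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        mean=float(x.mean()), sem=float(sd / np.sqrt(x.size)), n=int(x.size),
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p: float

    @property
    def tier(self) -> str:
        return significance_tier(self.p)


def welch_t_test(group_a, group_b) -> WelchResult:
    """Unpaired two-tailed t-test with Welch's correction.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from
    the t distribution.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            raise DegenerateInputError("both groups constant and equal")
        raise DegenerateInputError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def significance_tier(p: float) -> str:
    """Report tier: *** p<0.005, ** p<0.01, * p<0.05, else 'ns'."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
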