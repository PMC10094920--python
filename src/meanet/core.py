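"""Core containers: electrode layouts and spike rasters.

The recording geometry is a regular rectangular grid of extracellular
electrodes (e.g. a 64 x 64 CMOS array at 42 um pitch).  Positions are
expressed in millimetres relative to the centre of the arena, which for a
symmetric grid coincides with the centroid of the electrode positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["ElectrodeLayout", "SpikeRaster", "make_chip_layout"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """A regular electrode grid centred on the arena origin.

    Electrode ids run row-major from 0 to ``n_rows * n_cols - 1``.
    ``positions[i]`` is the (x, y) position of electrode ``i`` in mm,
    relative to the arena centre.
    """

    n_rows: int
    n_cols: int
    pitch_mm: float
    positions: np.ndarray = field(repr=False)

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def half_extent_mm(self) -> float:
        """Half-width of the larger grid dimension, in mm."""
        return max((self.n_rows - 1), (self.n_cols - 1)) * self.pitch_mm / 2.0

    def __eq__(self, other) -> bool:  # positions derive from the scalars
        if not isinstance(other, ElectrodeLayout):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.pitch_mm == other.pitch_mm
        )


def make_chip_layout(n_rows: int, n_cols: int, pitch_mm: float) -> ElectrodeLayout:
    """Build a centred rectangular electrode grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions; the full chip used here is 64 x 64 (4096 sites).
    pitch_mm:
        Centre-to-centre electrode spacing in mm (0.042 for the chip).

    The grid is symmetric about the origin, so the mean electrode position
    is (0, 0) up to floating-point rounding.
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidArgumentError(f"grid dimensions must be >= 1, got {n_rows}x{n_cols}")
    if pitch_mm <= 0:
        raise InvalidArgumentError(f"pitch must be positive, got {pitch_mm}")
    # integer level k maps to coordinate k * pitch / 2, with levels symmetric
    # about zero so positions come in exact +/- pairs
    col_levels = 2 * np.arange(n_cols) - (n_cols - 1)
    row_levels = 2 * np.arange(n_rows) - (n_rows - 1)
    xs = np.tile(col_levels, n_rows) * (pitch_mm / 2.0)
    ys = np.repeat(row_levels, n_cols) * (pitch_mm / 2.0)
    positions = np.column_stack([xs, ys])
    positions.setflags(write=False)
    return ElectrodeLayout(n_rows=n_rows, n_cols=n_cols, pitch_mm=pitch_mm, positions=positions)


@dataclass
class SpikeRaster:
    """All spike times of one recording, per electrode.

    ``spikes[i]`` is a sorted float array of spike times in seconds for
    electrode ``i``; silent electrodes have empty arrays.  ``meta`` carries
    provenance (condition, DIV, seed) when the raster is synthetic.
    """

    layout: ElectrodeLayout
    duration_s: float
    spikes: list[np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidArgumentError("duration must be positive")
        if len(self.spikes) != self.layout.n_electrodes:
            raise InvalidArgumentError(
                f"expected {self.layout.n_electrodes} spike trains, got {len(self.spikes)}"
            )
        self.spikes = [np.asarray(t, dtype=float) for t in self.spikes]

    @property
    def n_electrodes(self) -> int:
        return self.layout.n_electrodes

    def spike_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spikes])

    @property
    def n_spikes(self) -> int:
        return int(self.spike_counts().sum())

    def validate(self) -> None:
        """Check the container invariants; raise on violation."""
        for i, t in enumerate(self.spikes):
            if t.size == 0:
                continue
            if np.any(np.diff(t) < 0):
                raise InvalidArgumentError(f"electrode {i}: spike times not sorted")
            if t[0] < 0 or t[-1] >= self.duration_s:
                raise InvalidArgumentError(
                    f"electrode {i}: spike times outside [0, {self.duration_s})"
                )

    def equals(self, other: "SpikeRaster", atol: float = 0.0) -> bool:
        if self.layout != other.layout or self.duration_s != other.duration_s:
            return False
        for a, b in zip(self.spikes, other.spikes):
            if a.size != b.size:
                return False
            if a.size and not np.allclose(a, b, atol=atol, rtol=0.0):
                return False
        return True

    def events(self) -> tuple[np.ndarray, np.ndarray]:
        """Return all spikes as (times, electrode_ids), sorted by time."""
        if self.n_spikes == 0:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate(self.spikes)
        ids = np.concatenate(
            [np.full(t.size, i, dtype=int) for i, t in enumerate(self.spikes)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], ids[order]
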