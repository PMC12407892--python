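"""Spike-train container and binning.

A :class:`SpikeTrain` is an ordered list of spike times for one unit over a
known recording duration. All timescale analyses start from spike counts in
small time bins (5 ms by default), so binning is the only operation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "BinnedCounts", "bin_spikes", "DEFAULT_BIN_WIDTH"]

#: Default count bin width in seconds (5 ms).
DEFAULT_BIN_WIDTH = 0.005


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of a single unit.

    Parameters
    ----------
    unit_id : identifier of the unit.
    spike_times : 1-D array of spike times in seconds, nondecreasing.
    duration : recording duration in seconds; all spikes must lie in
        ``[0, duration]``.
    """

    unit_id: object
    spike_times: np.ndarray
    duration: float

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError("spike times must be nondecreasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class BinnedCounts:
    """Spike counts in consecutive bins of width ``bin_width`` seconds."""

    counts: np.ndarray
    bin_width: float
    unit_id: object = field(default=None)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def times(self) -> np.ndarray:
        """Left edges of the bins, in seconds."""
        return np.arange(self.n_bins) * self.bin_width


def bin_spikes(train: SpikeTrain, bin_width: float = DEFAULT_BIN_WIDTH) -> BinnedCounts:
    """Count spikes in half-open bins ``[i*dt, (i+1)*dt)``.

    The number of bins is ``floor(duration / bin_width)``; spikes at or
    beyond the last full bin edge are dropped (a spike exactly at
    ``duration`` never starts a partial bin).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if train.duration < bin_width:
        raise ValueError("duration shorter than one bin")
    n_bins = int(np.floor(train.duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.spike_times, bins=edges)
    # np.histogram closes the right edge of the last bin; enforce half-open.
    n_at_edge = int(np.sum(train.spike_times == edges[-1]))
    counts[-1] -= n_at_edge
    return BinnedCounts(counts=counts.astype(np.int64), bin_width=bin_width,
                        unit_id=train.unit_id)
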