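"""Spike-train binning and lagged-state assembly.

Spike trains are converted to binary series (a bin is 1 iff it contains at
least one spike, half-open bins ``[t0 + b*w, t0 + (b+1)*w)``).  Lagged
observations pair the receiver's future state I_F with its own immediately
preceding state I_P (self-lag one bin by default) and each source's state
J_P at a per-source delay, which is the substrate for all TE and PID
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "Timescale",
    "LaggedObservations",
    "bin_spikes",
    "lagged_observations",
    "SHORT_TIMESCALE",
    "LONG_TIMESCALE",
]


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times (seconds) over a recording interval."""

    trains: dict
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("empty recording interval")
        clean = {}
        for nid, times in self.trains.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < self.t_start or t.max() > self.t_end):
                raise ValueError(f"neuron {nid}: spike outside recording interval")
            if t.size and np.any(np.diff(t) < 0):
                t = np.sort(t)
            clean[nid] = t
        self.trains = clean

    @property
    def neuron_ids(self) -> list:
        return list(self.trains)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def rate(self, neuron_id) -> float:
        """Mean firing rate in Hz."""
        return len(self.trains[neuron_id]) / self.duration


@dataclass(frozen=True)
class Timescale:
    """A bin width plus the delays (in bins) enumerated at that width.

    The canonical short timescale (1.6 ms bins, delays 1-4) covers
    interactions from 1.6 to 6.4 ms; the long one (3.5 ms bins, delays 1-4)
    covers 3.5 to 14 ms, together spanning typical cortical synaptic delays.
    """

    bin_width_ms: float
    delays_bins: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if self.bin_width_ms <= 0:
            raise ValueError("bin width must be positive")
        if not self.delays_bins or any(d < 1 for d in self.delays_bins):
            raise ValueError("delays must be a nonempty list of positive ints")
        object.__setattr__(self, "delays_bins", tuple(int(d) for d in self.delays_bins))


SHORT_TIMESCALE = Timescale(1.6, (1, 2, 3, 4), "1.6-6.4ms")
LONG_TIMESCALE = Timescale(3.5, (1, 2, 3, 4), "3.5-14ms")


@dataclass
class LaggedObservations:
    """Rows of binary lagged states (I_F, I_P, J_P[, K_P, ...])."""

    receiver_id: object
    source_ids: tuple
    delays_bins: tuple[int, ...]
    states: np.ndarray  # (n_rows, 2 + n_sources) uint8
    variable_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.variable_names:
            extra = [f"J{j}_P" for j in range(len(self.source_ids))]
            if len(self.source_ids) == 1:
                extra = ["J_P"]
            elif len(self.source_ids) == 2:
                extra = ["J_P", "K_P"]
            self.variable_names = ("I_F", "I_P", *extra)

    @property
    def n_rows(self) -> int:
        return int(self.states.shape[0])


def bin_spikes(
    train: Sequence[float], bin_width_ms: float, t_start: float, t_end: float
) -> np.ndarray:
    """Binary series: bin b = 1 iff >= 1 spike in its half-open window."""
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    w = bin_width_ms / 1000.0
    # tolerate float dust so an interval of exactly k bins yields k bins
    n_bins = int(np.floor((t_end - t_start) / w + 1e-9))
    if n_bins <= 0:
        raise ValueError("empty binning interval")
    series = np.zeros(n_bins, dtype=np.uint8)
    t = np.asarray(train, dtype=float)
    if t.size:
        idx = np.floor((t - t_start) / w).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        series[idx] = 1
    return series


def lagged_observations(
    binned_receiver: np.ndarray,
    binned_sources: Sequence[np.ndarray] | Mapping[object, np.ndarray],
    delays_bins: Sequence[int],
    receiver_self_lag: int = 1,
    receiver_id=None,
    source_ids: Sequence | None = None,
    future_indices: np.ndarray | None = None,
) -> LaggedObservations:
    """Assemble (I_F, I_P, J_P, ...) rows for every admissible future bin.

    ``future_indices`` optionally restricts the future bins used (e.g. to a
    known motif clock); by default every bin with all lags inside the series
    contributes one row.
    """
    if isinstance(binned_sources, Mapping):
        source_ids = tuple(binned_sources)
        sources = [np.asarray(binned_sources[s]) for s in source_ids]
    else:
        sources = [np.asarray(s) for s in binned_sources]
        if source_ids is None:
            source_ids = tuple(range(len(sources)))
        else:
            source_ids = tuple(source_ids)
    receiver = np.asarray(binned_receiver)
    delays = tuple(int(d) for d in delays_bins)
    if len(delays) != len(sources):
        raise ValueError("need one delay per source")
    if any(d < 1 for d in delays) or receiver_self_lag < 1:
        raise ValueError("delays must be >= 1")
    n = receiver.shape[0]
    if any(s.shape[0] != n for s in sources):
        raise ValueError("all series must have the same length")
    max_lag = max((*delays, receiver_self_lag))
    if n <= max_lag:
        raise ValueError("series shorter than max delay + 1")
    if future_indices is None:
        fut = np.arange(max_lag, n)
    else:
        fut = np.asarray(future_indices, dtype=np.int64)
        fut = fut[(fut >= max_lag) & (fut < n)]
    cols = [receiver[fut], receiver[fut - receiver_self_lag]]
    cols += [s[fut - d] for s, d in zip(sources, delays)]
    states = np.stack(cols, axis=1).astype(np.uint8)
    return LaggedObservations(
        receiver_id=receiver_id,
        source_ids=source_ids,
        delays_bins=delays,
        states=states,
    )
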