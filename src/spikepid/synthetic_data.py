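"""Synthetic spike recordings with planted couplings and three-neuron motifs.

No public spike recordings accompany this kind of high-density culture
analysis, so every downstream stage is exercised on generated data: sparse
Poisson background trains (hour-scale, ~0.03-10 Hz), directed pairwise
couplings at millisecond delays, and three-neuron motifs whose lagged joint
state distribution is planted from one of eight canonical example columns
(no interaction, self, hidden self, single, redundant, single+redundant,
synergistic, synergistic+redundant).

Motif dynamics
--------------
A motif triad (J, K -> I) runs on a clock with one tick every
``delay_bins + 1`` bins.  At each tick one state tuple (i_F, i_P, j_P, k_P)
is drawn i.i.d. from the motif column and the four corresponding bins are
forced: J and K at lag ``delay_bins`` before the tick, I both at that lag
(its past state) and at the tick itself (its future state).  The stride
keeps the forced bins of consecutive ticks disjoint, so the lagged joint
distribution *at the motif clock* equals the planted column by construction.
Tick-to-tick draws must be independent because several columns (self,
hidden self) have a deterministic self-copy transition that would freeze a
single Markov realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import LaggedObservations, SpikeTrainSet, bin_spikes, lagged_observations
from .infotheory import JointDistribution

__all__ = [
    "MOTIF_NAMES",
    "MotifSpec",
    "SyntheticRecording",
    "table1_distribution",
    "sample_motif_states",
    "generate_recording",
    "random_network",
    "motif_tick_indices",
    "motif_observations",
    "write_recording",
    "read_spike_file",
]

_VARS = ("I_F", "I_P", "J_P", "K_P")

# The eight example joint distributions p(I_F, I_P, J_P, K_P), states in
# binary order 0000..1111.  Printed to four decimals where not an exact
# fraction; the synergistic_redundant column sums to 1.0002 as printed and
# is renormalized on construction.
_E = 1.0 / 16.0
_COLUMNS: dict[str, list[float]] = {
    "no_interaction": [_E] * 16,
    "self": [1 / 8] * 4 + [0.0] * 8 + [1 / 8] * 4,
    "hidden_self": [1 / 4, 1 / 4] + [0.0] * 12 + [1 / 4, 1 / 4],
    "single": [
        1 / 8, 1 / 8, 0, 0, 1 / 8, 1 / 8, 0, 0,
        0, 0, 1 / 8, 1 / 8, 0, 0, 1 / 8, 1 / 8,
    ],
    "redundant": [
        1 / 4, 0, 0, 0, 1 / 4, 0, 0, 0,
        0, 0, 0, 1 / 4, 0, 0, 0, 1 / 4,
    ],
    "single_redundant": [
        0.1964, 0.0536, 0, 0, 0.1964, 0.0536, 0, 0,
        0, 0, 0.0536, 0.1964, 0, 0, 0.0536, 0.1964,
    ],
    "synergistic": [
        1 / 8, 0, 0, 1 / 8, 1 / 8, 0, 0, 1 / 8,
        0, 1 / 8, 1 / 8, 0, 0, 1 / 8, 1 / 8, 0,
    ],
    "synergistic_redundant": [
        0.0548, 0.0548, 0.0548, 0, 0.0548, 0.0548, 0.0548, 0,
        0, 0, 0, 0.3357, 0, 0, 0, 0.3357,
    ],
}

MOTIF_NAMES = tuple(_COLUMNS)


def table1_distribution(motif_name: str) -> JointDistribution:
    """The example joint distribution for ``motif_name``, renormalized.

    Columns printed with rounded four-decimal masses do not sum exactly to
    one; masses are divided by their sum so the result is a proper pmf.
    """
    try:
        masses = np.array(_COLUMNS[motif_name], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown motif {motif_name!r}; expected one of {MOTIF_NAMES}"
        ) from None
    return JointDistribution(_VARS, (masses / masses.sum()).reshape((2, 2, 2, 2)))


def sample_motif_states(
    dist: JointDistribution, n_samples: int, seed
) -> np.ndarray:
    """``n_samples`` i.i.d. draws; rows are (i_F, i_P, j_P, k_P) in {0,1}."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(dist.variable_names)
    flat = dist.probs.ravel()
    codes = rng.choice(flat.size, size=n_samples, p=flat)
    bits = (codes[:, None] >> np.arange(k - 1, -1, -1)) & 1
    return bits.astype(np.uint8)


@dataclass(frozen=True)
class MotifSpec:
    """One planted triad interaction.

    ``base_rate_hz`` optionally adds Poisson background to the motif neurons
    in bins the motif clock does not force; it is 0 by default so the
    planted distribution stays clean.
    """

    motif_name: str
    delay_ms: float = 3.5
    bin_ms: float = 3.5
    base_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.motif_name not in _COLUMNS:
            raise ValueError(f"unknown motif {self.motif_name!r}")
        if not (0 < self.delay_ms <= 20):
            raise ValueError("delay_ms must lie in (0, 20]")
        if self.bin_ms <= 0 or self.base_rate_hz < 0:
            raise ValueError("bin_ms must be positive, base_rate_hz nonnegative")

    @property
    def delay_bins(self) -> int:
        d = int(round(self.delay_ms / self.bin_ms))
        return max(d, 1)


@dataclass
class SyntheticRecording:
    """Generated spike trains plus the ground truth that was planted."""

    spike_trains: SpikeTrainSet
    ground_truth_edges: list  # (source, target, delay_ms)
    ground_truth_motifs: list  # (J, K, I, MotifSpec)
    seed: int


def _poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def motif_tick_indices(spec: MotifSpec, n_bins: int) -> np.ndarray:
    """Future-bin indices of the motif clock (stride ``delay_bins + 1``)."""
    d = spec.delay_bins
    return np.arange(d, n_bins, d + 1, dtype=np.int64)


def generate_recording(
    n_neurons: int,
    duration_s: float,
    motif_specs=(),
    edge_specs=(),
    background_rate_hz: float = 2.0,
    seed: int = 0,
    edge_transmit_prob: float = 0.5,
    common_drive=None,
) -> SyntheticRecording:
    """Generate a recording with planted motifs and pairwise couplings.

    Parameters
    ----------
    motif_specs
        Iterable of ``(J, K, I, MotifSpec)`` triads; the neurons of a triad
        are reserved for the motif and receive no background.
    edge_specs
        Iterable of ``(source, target, delay_ms)``; each source spike
        induces a target spike ``delay_ms`` later with probability
        ``edge_transmit_prob`` (excess coincidences at the stated delay).
    common_drive
        Optional ``(period_s, depth)``: a network-wide fair binary signal
        redrawn every period scales background rates by ``1 +/- depth``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    motif_specs = list(motif_specs)
    edge_specs = list(edge_specs)
    rng = np.random.default_rng(seed)

    motif_neurons: set = set()
    for j, k, i, spec in motif_specs:
        for nid in (j, k, i):
            if nid >= n_neurons or nid < 0:
                raise ValueError(f"motif neuron {nid} out of range")
            if nid in motif_neurons:
                raise ValueError(f"neuron {nid} assigned to more than one motif")
            motif_neurons.add(nid)
    for s, t, _ in edge_specs:
        if s >= n_neurons or t >= n_neurons:
            raise ValueError("edge neuron index out of range")

    trains: dict[int, np.ndarray] = {}

    # independent Poisson background (optionally modulated by a common drive)
    for nid in range(n_neurons):
        if nid in motif_neurons:
            trains[nid] = np.empty(0)
            continue
        if common_drive is None:
            trains[nid] = _poisson_train(rng, background_rate_hz, duration_s)
        else:
            period_s, depth = common_drive
            n_per = int(np.ceil(duration_s / period_s))
            states = rng.integers(0, 2, size=n_per)
            parts = []
            for p, b in enumerate(states):
                rate = background_rate_hz * (1 + depth if b else 1 - depth)
                t0 = p * period_s
                seg = _poisson_train(rng, rate, min(period_s, duration_s - t0))
                parts.append(seg + t0)
            trains[nid] = np.sort(np.concatenate(parts)) if parts else np.empty(0)

    # planted triads: force bins from i.i.d. motif-clock draws
    for j, k, i, spec in motif_specs:
        w = spec.bin_ms / 1000.0
        n_bins = int(np.floor(duration_s / w))
        d = spec.delay_bins
        ticks = motif_tick_indices(spec, n_bins)
        draws = sample_motif_states(
            table1_distribution(spec.motif_name), ticks.size, rng
        )
        centers = (np.arange(n_bins) + 0.5) * w
        i_spikes = np.concatenate(
            [centers[ticks[draws[:, 0] == 1]], centers[ticks[draws[:, 1] == 1] - d]]
        )
        j_spikes = centers[ticks[draws[:, 2] == 1] - d]
        k_spikes = centers[ticks[draws[:, 3] == 1] - d]
        forced = {
            i: np.concatenate([ticks, ticks - d]),
            j: ticks - d,
            k: ticks - d,
        }
        for nid, sp in ((i, i_spikes), (j, j_spikes), (k, k_spikes)):
            if spec.base_rate_hz > 0:
                extra = _poisson_train(rng, spec.base_rate_hz, duration_s)
                bins_of_extra = np.floor(extra / w).astype(np.int64)
                keep = ~np.isin(bins_of_extra, forced[nid])
                sp = np.concatenate([sp, extra[keep]])
            trains[nid] = np.sort(sp)

    # pairwise couplings: source spikes induce delayed target spikes
    for s, t, delay_ms in edge_specs:
        src = trains[s]
        if src.size:
            transmitted = src[rng.random(src.size) < edge_transmit_prob]
            induced = transmitted + delay_ms / 1000.0
            induced = induced[induced < duration_s]
            trains[t] = np.sort(np.concatenate([trains[t], induced]))

    spike_trains = SpikeTrainSet(trains=trains, t_start=0.0, t_end=duration_s)
    return SyntheticRecording(
        spike_trains=spike_trains,
        ground_truth_edges=[(s, t, d) for s, t, d in edge_specs],
        ground_truth_motifs=motif_specs,
        seed=seed,
    )


def motif_observations(
    recording: SyntheticRecording, motif_index: int = 0
) -> LaggedObservations:
    """Lagged (I_F, I_P, J_P, K_P) rows of a planted triad at its clock.

    Bins the three motif neurons at the motif's bin width and restricts the
    future bins to the motif clock, with the receiver self-lag equal to the
    motif delay -- the estimand the generator plants.
    """
    j, k, i, spec = recording.ground_truth_motifs[motif_index]
    st = recording.spike_trains
    binned = {
        nid: bin_spikes(st.trains[nid], spec.bin_ms, st.t_start, st.t_end)
        for nid in (i, j, k)
    }
    n_bins = binned[i].shape[0]
    d = spec.delay_bins
    obs = lagged_observations(
        binned[i],
        [binned[j], binned[k]],
        delays_bins=(d, d),
        receiver_self_lag=d,
        receiver_id=i,
        source_ids=(j, k),
        future_indices=motif_tick_indices(spec, n_bins),
    )
    return obs


def random_network(n_nodes: int, n_edges: int, seed) -> list[tuple[int, int]]:
    """Uniform sample of ``n_edges`` distinct directed non-self edges."""
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(f"n_edges {n_edges} exceeds {max_edges}")
    rng = np.random.default_rng(seed)
    codes = rng.choice(max_edges, size=n_edges, replace=False)
    src = codes // (n_nodes - 1)
    rem = codes % (n_nodes - 1)
    dst = np.where(rem < src, rem, rem + 1)
    return list(zip(src.tolist(), dst.tolist()))


# ---------------------------------------------------------------------------
# plain-text IO

def write_recording(recording: SyntheticRecording, directory) -> dict[str, Path]:
    """Write spikes (TSV), edges and motifs (CSV) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    st = recording.spike_trains
    rows = [
        (nid, t) for nid in st.neuron_ids for t in st.trains[nid]
    ]
    rows.sort(key=lambda r: r[1])
    spike_path = directory / "spikes.tsv"
    with open(spike_path, "w") as fh:
        fh.write(f"# duration_s={st.duration}\tseed={recording.seed}\n")
        for nid, t in rows:
            fh.write(f"{nid}\t{t:.6f}\n")
    edges_path = directory / "ground_truth_edges.csv"
    pd.DataFrame(
        recording.ground_truth_edges, columns=["source", "target", "delay_ms"]
    ).to_csv(edges_path, index=False)
    motifs_path = directory / "ground_truth_motifs.csv"
    pd.DataFrame(
        [
            (j, k, i, m.motif_name, m.delay_ms, m.bin_ms, m.base_rate_hz)
            for j, k, i, m in recording.ground_truth_motifs
        ],
        columns=["J", "K", "I", "motif_name", "delay_ms", "bin_ms", "base_rate_hz"],
    ).to_csv(motifs_path, index=False)
    return {"spikes": spike_path, "edges": edges_path, "motifs": motifs_path}


def read_spike_file(path) -> SpikeTrainSet:
    """Read the two-column ``neuron_id<TAB>time_seconds`` format."""
    path = Path(path)
    duration = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("duration_s="):
                    duration = float(tok.split("=", 1)[1])
            df = pd.read_csv(path, sep="\t", comment="#", header=None,
                             names=["neuron_id", "time"])
        else:
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["neuron_id", "time"])
    if duration is None:
        duration = float(df["time"].max()) if len(df) else 0.0
    trains = {
        int(nid): np.sort(g["time"].to_numpy())
        for nid, g in df.groupby("neuron_id")
    }
    return SpikeTrainSet(trains=trains, t_start=0.0, t_end=duration)
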