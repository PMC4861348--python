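"""Does a neuron's network position predict how much it computes?

For every receiver with two or more significant incoming connections, every
unordered pair of its inputs forms a triad; the triad's normalized PID
synergy is the computation the receiver performs on that input pair.  Two
correlations are then examined across triads: synergy against the
receiver's in-degree (one point per triad) and synergy against the
transmitters' out-degrees (two points per triad, one per transmitter).  A
shuffle null (degree/synergy pairings permuted) calibrates the individual
correlations, and a binomial sign-skew test asks whether positive
correlations outnumber negative ones across recordings more than chance
allows.  Higher-order computation is profiled by fitting an exponential
decay to the median information gain as a function of the number of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .binning import SpikeTrainSet, Timescale, bin_spikes, lagged_observations
from .network_inference import EffectiveNetwork
from .pid import InfoGainResult, information_gain, pid_from_observations

__all__ = [
    "TriadRecord",
    "enumerate_triads",
    "compute_triad_synergies",
    "degree_synergy_correlation",
    "shuffled_null",
    "correlation_skew_test",
    "synergy_vs_degree_profile",
    "receiver_info_gains",
    "info_gain_decay_fit",
]


@dataclass
class TriadRecord:
    """One (J, K -> receiver) group with its synergy and the three degrees."""

    receiver: object
    J: object
    K: object
    synergy_normalized: float
    receiver_in_degree: int
    J_out_degree: int
    K_out_degree: int


def enumerate_triads(network: EffectiveNetwork) -> list[TriadRecord]:
    """All C(in-degree, 2) input pairs per receiver, synergy unfilled (nan)."""
    g = network.graph
    triads = []
    for receiver in g.nodes:
        preds = sorted(g.predecessors(receiver), key=repr)
        for j, k in combinations(preds, 2):
            triads.append(
                TriadRecord(
                    receiver=receiver,
                    J=j,
                    K=k,
                    synergy_normalized=float("nan"),
                    receiver_in_degree=g.in_degree(receiver),
                    J_out_degree=g.out_degree(j),
                    K_out_degree=g.out_degree(k),
                )
            )
    return triads


def compute_triad_synergies(
    network: EffectiveNetwork,
    spikes: SpikeTrainSet,
    timescale: Timescale,
    self_lag: int = 1,
) -> list[TriadRecord]:
    """Fill triad synergies with the PID at each edge's detected delay.

    Each source enters the triad distribution at the delay that maximized
    its bivariate TE, so the bivariate TE terms of the decomposition match
    the pairwise inference stage.
    """
    triads = enumerate_triads(network)
    binned = {
        nid: bin_spikes(spikes.trains[nid], timescale.bin_width_ms,
                        spikes.t_start, spikes.t_end)
        for nid in spikes.neuron_ids
    }
    for tr in triads:
        obs = lagged_observations(
            binned[tr.receiver],
            [binned[tr.J], binned[tr.K]],
            delays_bins=(
                network.edge_delay(tr.J, tr.receiver),
                network.edge_delay(tr.K, tr.receiver),
            ),
            receiver_self_lag=self_lag,
            receiver_id=tr.receiver,
            source_ids=(tr.J, tr.K),
        )
        res = pid_from_observations(obs)
        tr.synergy_normalized = res.normalized("synergy")
    return triads


def _points(triads: Sequence[TriadRecord], mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "in":
        syn = np.array([t.synergy_normalized for t in triads])
        deg = np.array([t.receiver_in_degree for t in triads], dtype=float)
    elif mode == "out":
        syn = np.array(
            [t.synergy_normalized for t in triads for _ in (0, 1)]
        )
        deg = np.array(
            [d for t in triads for d in (t.J_out_degree, t.K_out_degree)],
            dtype=float,
        )
    else:
        raise ValueError("mode must be 'in' or 'out'")
    return syn, deg


def degree_synergy_correlation(
    triads: Sequence[TriadRecord], mode: str, method: str = "pearson"
) -> float:
    """Correlation between triad synergy and degree (nan if degenerate).

    ``mode='in'`` pairs each triad's synergy with the receiver in-degree;
    ``mode='out'`` contributes two points per triad, one per transmitter.
    """
    syn, deg = _points(triads, mode)
    if syn.size < 3:
        raise ValueError("need at least 3 data points")
    if np.std(syn) == 0 or np.std(deg) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(deg, syn).statistic)
    if method == "spearman":
        return float(stats.spearmanr(deg, syn).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")


def shuffled_null(
    triads: Sequence[TriadRecord],
    mode: str,
    n_shuffles: int = 400,
    seed=0,
    method: str = "pearson",
) -> np.ndarray:
    """Null correlations from randomized degree/synergy pairings."""
    syn, deg = _points(triads, mode)
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(n_shuffles):
        out[i] = corr(deg, rng.permutation(syn)).statistic
    return out


def correlation_skew_test(
    correlation_values: Sequence[float],
) -> tuple[int, int, float]:
    """Sign skew of per-recording correlations under a fair-coin null.

    Returns (n_positive, n_negative, p) where p is the one-sided binomial
    tail probability of seeing at least ``max(n_pos, n_neg)`` same-sign
    outcomes in ``n_pos + n_neg`` trials at probability 1/2.  Zero and nan
    correlations are excluded; an empty count gives p = nan.
    """
    vals = np.asarray(list(correlation_values), dtype=float)
    vals = vals[np.isfinite(vals) & (vals != 0)]
    n_pos = int((vals > 0).sum())
    n_neg = int((vals < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        return 0, 0, float("nan")
    k = max(n_pos, n_neg)
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return n_pos, n_neg, p


def synergy_vs_degree_profile(
    triads: Sequence[TriadRecord], mode: str, min_group: int = 20
) -> pd.DataFrame:
    """Median and quartiles of synergy per degree (sparse degrees omitted)."""
    syn, deg = _points(triads, mode)
    rows = []
    for d in np.unique(deg):
        vals = syn[deg == d]
        if vals.size < min_group:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((int(d), int(vals.size), q1, med, q3))
    return pd.DataFrame(rows, columns=["degree", "n", "q1", "median", "q3"])


def receiver_info_gains(
    network: EffectiveNetwork,
    spikes: SpikeTrainSet,
    timescale: Timescale,
    n_inputs: int,
    max_combinations: int = 100,
    seed=0,
    self_lag: int = 1,
) -> list[InfoGainResult]:
    """Information gain of the n-th input for every eligible receiver."""
    g = network.graph
    binned = {
        nid: bin_spikes(spikes.trains[nid], timescale.bin_width_ms,
                        spikes.t_start, spikes.t_end)
        for nid in spikes.neuron_ids
    }
    rng = np.random.default_rng(seed)
    results = []
    for receiver in g.nodes:
        preds = sorted(g.predecessors(receiver), key=repr)
        if len(preds) < n_inputs:
            continue
        obs = lagged_observations(
            binned[receiver],
            [binned[p] for p in preds],
            delays_bins=[network.edge_delay(p, receiver) for p in preds],
            receiver_self_lag=self_lag,
            receiver_id=receiver,
            source_ids=tuple(preds),
        )
        results.append(
            information_gain(obs, n_inputs, max_combinations,
                             seed=rng.integers(2**31))
        )
    return results


def info_gain_decay_fit(
    info_gain_results: Iterable[InfoGainResult],
) -> tuple[float, float, tuple[float, float]]:
    """Fit median gain vs number of inputs with a * exp(b * n).

    Returns (amplitude, exponent, 95% CI on the exponent); a negative
    exponent means the bound on the highest-order computation shrinks as
    inputs are added.
    """
    by_n: dict[int, list[float]] = {}
    for r in info_gain_results:
        by_n.setdefault(r.n_inputs, []).append(r.mean_gain_bits)
    ns = np.array(sorted(by_n))
    if ns.size < 3:
        raise ValueError("need medians at >= 3 input counts")
    medians = np.array([np.median(by_n[n]) for n in ns])

    def model(n, a, b):
        return a * np.exp(b * n)

    b0 = 0.0
    if medians[0] > 0 and medians[-1] > 0:
        b0 = (np.log(medians[-1]) - np.log(medians[0])) / (ns[-1] - ns[0])
    popt, pcov = curve_fit(model, ns, medians, p0=(max(medians[0], 1e-12), b0),
                           maxfev=20000)
    a, b = float(popt[0]), float(popt[1])
    se_b = float(np.sqrt(max(pcov[1, 1], 0.0)))
    dof = max(ns.size - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    return a, b, (b - tcrit * se_b, b + tcrit * se_b)
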