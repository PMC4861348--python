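"""Partial information decomposition of multivariate transfer entropy.

The information two source neurons J and K carry about a receiver I's next
state decomposes into four nonnegative parts,

    TE({J,K} -> I) = Synergy + Unique_J + Unique_K + Redundancy
    TE(J -> I)     = Unique_J + Redundancy
    TE(K -> I)     = Unique_K + Redundancy

with redundancy measured by the minimum information I_min: an expectation,
over receiver future states, of the smaller of the two source-specific
informations (each conditioned on the receiver's own past).  The synergy
term -- information available only from joint knowledge of both sources --
is interpreted throughout this package as the computation performed by the
receiver.  Interaction information is provided as the classical contrast:
it conflates synergy (positive) and redundancy (negative) into one signed
number, which is exactly what the decomposition avoids.

For more than two sources the full decomposition is impractical (the number
of lattice terms explodes), but the highest-order synergy is bounded by the
information gained when the n-th input is added:

    I_gain = TE({J_1..J_n} -> I) - TE({J_1..J_{n-1}} -> I) >= Synergy_n

averaged here over the n leave-one-out choices of the excluded input and
over at most 100 sampled input combinations per receiver.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .binning import LaggedObservations
from .infotheory import (
    JointDistribution,
    conditional_mutual_information,
    entropy,
    estimate_distribution,
    mutual_information,
)

__all__ = [
    "PIDResult",
    "InfoGainResult",
    "specific_information",
    "imin_redundancy",
    "pid_decompose",
    "pid_from_observations",
    "interaction_information",
    "information_gain",
]

_DUST = 1e-9


@dataclass(frozen=True)
class PIDResult:
    """Decomposition of TE({J,K}->I), raw bits and entropy-normalized."""

    receiver: object = None
    source_J: object = None
    source_K: object = None
    te_joint: float = 0.0
    te_J: float = 0.0
    te_K: float = 0.0
    redundancy: float = 0.0
    unique_J: float = 0.0
    unique_K: float = 0.0
    synergy: float = 0.0
    h_receiver_future: float = 0.0
    delay_J: int | None = None
    delay_K: int | None = None

    def normalized(self, term: str) -> float:
        """A term divided by H(I_F) (0 when the receiver future is constant)."""
        value = getattr(self, term)
        return value / self.h_receiver_future if self.h_receiver_future > 0 else 0.0


@dataclass(frozen=True)
class InfoGainResult:
    receiver: object
    n_inputs: int
    mean_gain_bits: float
    n_combinations_sampled: int


def specific_information(
    dist: JointDistribution, i_f_value: int, R_vars: Sequence[str]
) -> float:
    """Information the variables (R, I_P) provide about the event I_F = i_F.

    With empty ``R_vars`` this is the self-past specific information
    I_spec(I_F = i_F; I_P).
    """
    cond_vars = tuple(R_vars) + ("I_P",)
    joint = dist.marginal(("I_F",) + cond_vars)
    p = joint.probs
    p_if = p.sum(axis=tuple(range(1, p.ndim)))[i_f_value]
    if p_if <= 0:
        raise ValueError(f"I_F = {i_f_value} has zero marginal mass")
    slice_if = p[i_f_value]  # p(r, i_P, I_F = i_f)
    p_cond = p.sum(axis=0)  # p(r, i_P)
    mask = slice_if > 0
    ratio = slice_if[mask] / (p_cond[mask] * p_if)
    weights = slice_if[mask] / p_if  # p(r, i_P | i_F)
    return float((weights * np.log2(ratio)).sum())


def imin_redundancy(dist: JointDistribution) -> float:
    """I_min redundancy of {J_P, K_P} about I_F, conditioned on I_P."""
    p_if = dist.marginal(("I_F",)).probs
    total = 0.0
    for i_f in (0, 1):
        if p_if[i_f] <= 0:
            continue
        base = specific_information(dist, i_f, ())
        terms = [
            specific_information(dist, i_f, (r,)) - base
            for r in ("J_P", "K_P")
        ]
        total += p_if[i_f] * min(terms)
    return max(0.0, total)


def _clamp(x: float) -> float:
    if x < -_DUST:
        return x  # genuinely negative: surface it, don't hide
    return max(0.0, x)


def pid_decompose(
    dist: JointDistribution,
    receiver=None,
    source_J=None,
    source_K=None,
    delay_J: int | None = None,
    delay_K: int | None = None,
) -> PIDResult:
    """Full two-source decomposition from a (I_F, I_P, J_P, K_P) pmf."""
    need = {"I_F", "I_P", "J_P", "K_P"}
    if not need <= set(dist.variable_names):
        raise ValueError(f"distribution must contain variables {sorted(need)}")
    te_J = conditional_mutual_information(dist, ("I_F",), ("J_P",), ("I_P",))
    te_K = conditional_mutual_information(dist, ("I_F",), ("K_P",), ("I_P",))
    te_joint = conditional_mutual_information(
        dist, ("I_F",), ("J_P", "K_P"), ("I_P",)
    )
    redundancy = imin_redundancy(dist)
    unique_J = _clamp(te_J - redundancy)
    unique_K = _clamp(te_K - redundancy)
    synergy = _clamp(te_joint - redundancy - unique_J - unique_K)
    return PIDResult(
        receiver=receiver,
        source_J=source_J,
        source_K=source_K,
        te_joint=te_joint,
        te_J=te_J,
        te_K=te_K,
        redundancy=redundancy,
        unique_J=unique_J,
        unique_K=unique_K,
        synergy=synergy,
        h_receiver_future=entropy(dist, ("I_F",)),
        delay_J=delay_J,
        delay_K=delay_K,
    )


def pid_from_observations(obs: LaggedObservations) -> PIDResult:
    """Estimate the joint pmf from lagged rows, then decompose."""
    if len(obs.source_ids) != 2:
        raise ValueError("PID needs exactly two sources")
    dist = estimate_distribution(obs)
    return pid_decompose(
        dist,
        receiver=obs.receiver_id,
        source_J=obs.source_ids[0],
        source_K=obs.source_ids[1],
        delay_J=obs.delays_bins[0],
        delay_K=obs.delays_bins[1],
    )


def interaction_information(dist: JointDistribution) -> float:
    """II(J_P; K_P; I_F) = MI(J_P; K_P | I_F) - MI(J_P; K_P).

    Positive when synergy dominates, negative when redundancy dominates; a
    mixture of both can cancel to near zero, which is why the decomposition
    is needed.
    """
    return conditional_mutual_information(
        dist, ("J_P",), ("K_P",), ("I_F",)
    ) - mutual_information(dist, ("J_P",), ("K_P",))


def _joint_te_from_states(states: np.ndarray, col_subset: Sequence[int]) -> float:
    """TE({selected sources} -> I) from raw binary rows.

    Column 0 is I_F, column 1 is I_P, remaining columns are sources.
    """
    cols = [0, 1] + list(col_subset)
    sub = states[:, cols]
    k = sub.shape[1]
    names = ("I_F", "I_P") + tuple(f"S{j}" for j in range(k - 2))
    obs = LaggedObservations(
        receiver_id=None,
        source_ids=tuple(range(k - 2)),
        delays_bins=(1,) * (k - 2),
        states=sub,
        variable_names=names,
    )
    dist = estimate_distribution(obs)
    return conditional_mutual_information(dist, ("I_F",), names[2:], ("I_P",))


def information_gain(
    observations: LaggedObservations,
    n: int,
    max_combinations: int = 100,
    seed=0,
) -> InfoGainResult:
    """Mean information gained by the n-th input, over sampled input sets.

    For each sampled size-n set of the receiver's inputs the gain is the
    joint TE of all n sources minus the mean of the n leave-one-out joint
    TEs; gains are then averaged across sets.  All ``C(m, n)`` sets are used
    when there are no more than ``max_combinations`` of them, otherwise that
    many are sampled without replacement.
    """
    m = len(observations.source_ids)
    if not (2 <= n <= 6):
        raise ValueError("n must be between 2 and 6")
    if m < n:
        raise ValueError(f"receiver has {m} inputs, need at least {n}")
    all_combos = list(combinations(range(2, 2 + m), n))
    if len(all_combos) > max_combinations:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_combos), size=max_combinations, replace=False)
        combos = [all_combos[i] for i in sorted(idx)]
    else:
        combos = all_combos
    states = observations.states
    gains = []
    for combo in combos:
        te_full = _joint_te_from_states(states, combo)
        loo = [
            _joint_te_from_states(states, [c for c in combo if c != excl])
            for excl in combo
        ]
        gains.append(te_full - float(np.mean(loo)))
    return InfoGainResult(
        receiver=observations.receiver_id,
        n_inputs=n,
        mean_gain_bits=float(np.mean(gains)),
        n_combinations_sampled=len(combos),
    )
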