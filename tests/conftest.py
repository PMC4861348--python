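"""Shared fixtures and an independent brute-force information oracle.

The oracle works on plain ``{state_tuple: probability}`` dicts with pure
Python arithmetic (no numpy, no package code), enumerating all 16 states
of (I_F, I_P, J_P, K_P) directly from the defining sums.  It exists to
cross-check the production vectorized path and must stay independent of it.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest

AXES = {"I_F": 0, "I_P": 1, "J_P": 2, "K_P": 3}


def dist_to_dict(dist) -> dict:
    """Convert a package JointDistribution over 4 binary vars to a dict."""
    return {
        s: float(dist.probs[s]) for s in product((0, 1), repeat=dist.probs.ndim)
    }


def o_marginal(p: dict, axes: tuple[int, ...]) -> dict:
    out: dict = {}
    for state, mass in p.items():
        key = tuple(state[a] for a in axes)
        out[key] = out.get(key, 0.0) + mass
    return out


def o_entropy(p: dict, axes: tuple[int, ...]) -> float:
    m = o_marginal(p, axes)
    return -sum(v * math.log2(v) for v in m.values() if v > 0)


def o_mi(p: dict, ax: tuple[int, ...], ay: tuple[int, ...]) -> float:
    pxy = o_marginal(p, ax + ay)
    px = o_marginal(p, ax)
    py = o_marginal(p, ay)
    total = 0.0
    for state, mass in pxy.items():
        if mass <= 0:
            continue
        x, y = state[: len(ax)], state[len(ax):]
        total += mass * math.log2(mass / (px[x] * py[y]))
    return total


def o_cmi(p: dict, ax, ay, az) -> float:
    """MI(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)."""
    return (
        o_entropy(p, ax + az) + o_entropy(p, ay + az)
        - o_entropy(p, ax + ay + az) - o_entropy(p, az)
    )


def o_ispec(p: dict, i_f: int, r_axes: tuple[int, ...]) -> float:
    """Specific information of (R, I_P) about the event I_F = i_f."""
    axes = r_axes + (AXES["I_P"],)
    joint = o_marginal(p, (AXES["I_F"],) + axes)  # (i_f, r..., i_p)
    cond = o_marginal(p, axes)
    p_if = o_marginal(p, (AXES["I_F"],))[(i_f,)]
    total = 0.0
    for state, mass in joint.items():
        if state[0] != i_f or mass <= 0:
            continue
        rest = state[1:]
        total += (mass / p_if) * math.log2(mass / (cond[rest] * p_if))
    return total


def o_imin(p: dict) -> float:
    p_if = o_marginal(p, (AXES["I_F"],))
    total = 0.0
    for i_f in (0, 1):
        if p_if[(i_f,)] <= 0:
            continue
        base = o_ispec(p, i_f, ())
        diffs = [
            o_ispec(p, i_f, (AXES[r],)) - base for r in ("J_P", "K_P")
        ]
        total += p_if[(i_f,)] * min(diffs)
    return total


def o_pid(p: dict) -> dict:
    te_j = o_cmi(p, (0,), (2,), (1,))
    te_k = o_cmi(p, (0,), (3,), (1,))
    te_joint = o_cmi(p, (0,), (2, 3), (1,))
    red = o_imin(p)
    uj = te_j - red
    uk = te_k - red
    return {
        "te_J": te_j,
        "te_K": te_k,
        "te_joint": te_joint,
        "redundancy": red,
        "unique_J": uj,
        "unique_K": uk,
        "synergy": te_joint - red - uj - uk,
    }


def o_ii(p: dict) -> float:
    return o_cmi(p, (2,), (3,), (0,)) - o_mi(p, (2,), (3,))


def random_distribution(rng: np.random.Generator) -> np.ndarray:
    """A random pmf over the 16 joint states (Dirichlet, occasionally sparse)."""
    alpha = rng.choice([0.2, 1.0, 3.0])
    p = rng.dirichlet(np.full(16, alpha))
    return p.reshape(2, 2, 2, 2)


@pytest.fixture(scope="session")
def motif_names():
    from spikepid import MOTIF_NAMES

    return MOTIF_NAMES
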