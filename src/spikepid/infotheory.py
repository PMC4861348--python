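"""Discrete information measures over binary lagged-state distributions.

All measures are plug-in (maximum-likelihood) estimates in base 2 (bits),
with the conventions 0*log(0) := 0 and zero-mass conditioning terms
contributing nothing.  Transfer entropy from a source J to a receiver I is
the conditional mutual information between the source past J_P and the
receiver future I_F given the receiver's own past I_P,

    TE(J -> I) = MI(I_F ; J_P | I_P),

optionally normalized by the receiver-future entropy H(I_F) so that values
are comparable across neurons with different firing rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "JointDistribution",
    "TEResult",
    "estimate_distribution",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "transfer_entropy",
    "multivariate_transfer_entropy",
]


@dataclass(frozen=True)
class JointDistribution:
    """A probability mass function over tuples of binary variables.

    Parameters
    ----------
    variable_names
        Ordered names, e.g. ``("I_F", "I_P", "J_P", "K_P")``.
    probs
        Array of shape ``(2,) * len(variable_names)``; ``probs[s]`` is the
        mass of state tuple ``s``.
    """

    variable_names: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2,) * len(self.variable_names):
            raise ValueError(
                f"probs shape {p.shape} does not match "
                f"{len(self.variable_names)} binary variables"
            )
        if np.any(p < -1e-12):
            raise ValueError("negative probability mass")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"masses sum to {total}, not 1")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))

    @classmethod
    def from_masses(
        cls,
        variable_names: Sequence[str],
        masses: Mapping[tuple[int, ...], float],
        normalize: bool = False,
    ) -> "JointDistribution":
        """Build from a sparse ``{state_tuple: mass}`` mapping."""
        k = len(variable_names)
        p = np.zeros((2,) * k)
        for state, mass in masses.items():
            p[tuple(state)] = mass
        if normalize:
            p = p / p.sum()
        return cls(tuple(variable_names), p)

    def prob(self, state: tuple[int, ...]) -> float:
        return float(self.probs[tuple(state)])

    def _axes(self, variables: Iterable[str]) -> tuple[int, ...]:
        idx = {name: i for i, name in enumerate(self.variable_names)}
        try:
            return tuple(idx[v] for v in variables)
        except KeyError as exc:
            raise KeyError(f"unknown variable {exc.args[0]!r}") from None

    def marginal(self, variables: Sequence[str]) -> "JointDistribution":
        """Marginalize onto ``variables`` (kept in the given order)."""
        keep = self._axes(variables)
        drop = tuple(i for i in range(len(self.variable_names)) if i not in keep)
        p = self.probs.sum(axis=drop) if drop else self.probs
        # reorder remaining axes to match the requested order
        remaining = [i for i in range(len(self.variable_names)) if i in keep]
        order = [remaining.index(i) for i in keep]
        return JointDistribution(tuple(variables), np.transpose(p, order))


@dataclass(frozen=True)
class TEResult:
    """Transfer entropy for one directed pair at one timescale."""

    source: object
    target: object
    timescale: str
    delay_bins: int
    te_bits: float
    te_normalized: float
    n_observations: int


def estimate_distribution(observations) -> JointDistribution:
    """Plug-in joint distribution from a table of binary observations.

    ``observations`` is a :class:`~spikepid.binning.LaggedObservations` or any
    object with ``states`` (an (n, k) binary array) and ``variable_names``.
    """
    states = np.asarray(observations.states)
    if states.size == 0:
        raise ValueError("no observations")
    n, k = states.shape
    codes = states @ (1 << np.arange(k - 1, -1, -1))
    counts = np.bincount(codes, minlength=2**k).astype(float)
    probs = (counts / n).reshape((2,) * k)
    return JointDistribution(tuple(observations.variable_names), probs)


def _entropy_of_array(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy(dist: JointDistribution, variables: Sequence[str] | None = None) -> float:
    """Shannon entropy (bits) of the marginal on ``variables``."""
    if variables is None:
        variables = dist.variable_names
    if len(tuple(variables)) == 0:
        raise ValueError("empty variable set")
    return _entropy_of_array(dist.marginal(tuple(variables)).probs.ravel())


def mutual_information(
    dist: JointDistribution, x_vars: Sequence[str], y_vars: Sequence[str]
) -> float:
    """MI(X; Y) in bits; symmetric and nonnegative."""
    x, y = tuple(x_vars), tuple(y_vars)
    if set(x) & set(y):
        raise ValueError("X and Y overlap")
    h_x = entropy(dist, x)
    h_y = entropy(dist, y)
    h_xy = entropy(dist, x + y)
    return max(0.0, h_x + h_y - h_xy)


def conditional_mutual_information(
    dist: JointDistribution,
    x_vars: Sequence[str],
    y_vars: Sequence[str],
    z_vars: Sequence[str],
) -> float:
    """MI(X; Y | Z) in bits; reduces to MI(X; Y) for empty Z."""
    x, y, z = tuple(x_vars), tuple(y_vars), tuple(z_vars)
    sets = [set(x), set(y), set(z)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError("variable sets overlap")
    if not z:
        return mutual_information(dist, x, y)
    h_xz = entropy(dist, x + z)
    h_yz = entropy(dist, y + z)
    h_xyz = entropy(dist, x + y + z)
    h_z = entropy(dist, z)
    return max(0.0, h_xz + h_yz - h_xyz - h_z)


def _te_from_distribution(
    dist: JointDistribution, source_vars: Sequence[str]
) -> tuple[float, float]:
    te = conditional_mutual_information(dist, ("I_F",), tuple(source_vars), ("I_P",))
    h_f = entropy(dist, ("I_F",))
    te_norm = te / h_f if h_f > 0 else 0.0
    return te, float(np.clip(te_norm, 0.0, 1.0))


def transfer_entropy(observations, timescale: str = "", delay_bins: int = 0) -> TEResult:
    """Bivariate TE from lagged observations over (I_F, I_P, J_P)."""
    names = tuple(observations.variable_names)
    if names != ("I_F", "I_P", "J_P"):
        raise ValueError(f"expected variables (I_F, I_P, J_P), got {names}")
    dist = estimate_distribution(observations)
    te, te_norm = _te_from_distribution(dist, ("J_P",))
    return TEResult(
        source=getattr(observations, "source_ids", (None,))[0],
        target=getattr(observations, "receiver_id", None),
        timescale=timescale,
        delay_bins=delay_bins,
        te_bits=te,
        te_normalized=te_norm,
        n_observations=observations.states.shape[0],
    )


def multivariate_transfer_entropy(dist: JointDistribution) -> float:
    """Joint TE (bits) from all source-past variables to I_F given I_P."""
    sources = tuple(
        v for v in dist.variable_names if v not in ("I_F", "I_P")
    )
    if not sources:
        raise ValueError("distribution has no source variables")
    return conditional_mutual_information(dist, ("I_F",), sources, ("I_P",))
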