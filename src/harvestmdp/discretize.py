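"""State grids, quadrature discretization of normal noise, and kernels.

Continuous population dynamics are turned into finite transition matrices
in three steps: (1) each state variable lives on a uniform grid; (2) each
normal process error is replaced by a small Gauss-Hermite rule (nodes and
probabilities that match the normal's moments); (3) every next-state draw
is projected back onto the grid by a mean-preserving two-point linear
split between the bracketing nodes, clamping outcomes that leave the grid
to the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import roots_hermitenorm

from .errors import ValidationError

__all__ = [
    "Grid1D",
    "DiscreteNoise",
    "build_grid",
    "gauss_hermite",
    "project_to_grid",
    "projection_split",
    "build_kernel",
]


@dataclass(frozen=True)
class Grid1D:
    """A strictly increasing, uniformly spaced inclusive grid."""

    values: np.ndarray
    step: float
    lower: float
    upper: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("grid needs at least two points")
        d = np.diff(v)
        if d.min() <= 0 or np.abs(d - self.step).max() > 1e-12 * max(1.0, abs(self.step)):
            raise ValidationError("grid must be strictly increasing with uniform spacing")

    @property
    def n(self) -> int:
        return self.values.size

    def index_of(self, value: float, tol: float = 1e-9) -> int:
        """Index of the grid point equal to ``value`` (within ``tol``)."""
        i = int(np.argmin(np.abs(self.values - value)))
        if abs(self.values[i] - value) > tol:
            raise ValidationError(f"{value} is not a grid point")
        return i


def build_grid(lower: float, upper: float, step: float) -> Grid1D:
    """Inclusive uniform grid from ``lower`` to ``upper`` in steps of ``step``."""
    if step <= 0:
        raise ValidationError("step must be positive")
    if upper <= lower:
        raise ValidationError("upper must exceed lower")
    n_steps = (upper - lower) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValidationError(
            f"interval [{lower}, {upper}] is not an integer number of steps of {step}"
        )
    n = int(round(n_steps)) + 1
    values = lower + step * np.arange(n)
    return Grid1D(values=values, step=float(step), lower=float(lower), upper=float(upper))


@dataclass(frozen=True)
class DiscreteNoise:
    """A finite set of noise realizations with probabilities summing to 1."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValidationError("nodes and weights must be matching 1-d arrays")
        if weights.min() <= 0:
            raise ValidationError("weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must sum to 1")

    @property
    def mean(self) -> float:
        return float(self.weights @ self.nodes)

    @property
    def variance(self) -> float:
        return float(self.weights @ (self.nodes - self.mean) ** 2)


def gauss_hermite(mean: float, variance: float, n_nodes: int) -> DiscreteNoise:
    """Probabilists' Gauss-Hermite rule rescaled to N(mean, variance).

    The rule integrates polynomials of degree <= 2 n - 1 exactly, so the
    discrete distribution reproduces the normal's mean and variance for
    any ``n_nodes >= 2`` (and collapses to a point mass at the mean for
    ``n_nodes = 1``).
    """
    if variance <= 0:
        raise ValidationError("variance must be positive")
    if n_nodes < 1:
        raise ValidationError("need at least one node")
    if n_nodes == 1:
        return DiscreteNoise(nodes=np.array([mean]), weights=np.array([1.0]))
    x, w = roots_hermitenorm(n_nodes)
    weights = w / w.sum()  # normalizes the sqrt(2 pi) weight-function mass
    nodes = mean + np.sqrt(variance) * x
    return DiscreteNoise(nodes=nodes, weights=weights)


def projection_split(values: np.ndarray, grid: Grid1D):
    """Vectorized two-point projection of arbitrary values onto a grid.

    Returns ``(lo, w_lo)``: the index of the lower bracketing node and the
    probability mass it receives; index ``lo + 1`` receives ``1 - w_lo``.
    Values outside the grid are clamped to the nearest boundary node.  The
    split is proportional to proximity, so it preserves the mean of
    interior values.
    """
    values = np.asarray(values, dtype=float)
    lo = np.clip(
        np.floor((values - grid.lower) / grid.step).astype(int), 0, grid.n - 2
    )
    frac = np.clip((values - grid.values[lo]) / grid.step, 0.0, 1.0)
    return lo, 1.0 - frac


def project_to_grid(value: float, grid: Grid1D):
    """Probability split of a scalar value over grid indices.

    Returns ``(indices, masses)`` with masses summing to 1; a single
    entry for on-node or out-of-range (clamped) values, two entries for
    interior values.
    """
    lo, w_lo = projection_split(np.array([value]), grid)
    lo, w_lo = int(lo[0]), float(w_lo[0])
    if w_lo >= 1.0:
        return np.array([lo]), np.array([1.0])
    if w_lo <= 0.0:
        return np.array([lo + 1]), np.array([1.0])
    return np.array([lo, lo + 1]), np.array([w_lo, 1.0 - w_lo])


def build_kernel(
    next_state_fn: Callable,
    grids: Sequence[Grid1D],
    noises: Sequence[DiscreteNoise],
    n_actions: int,
) -> list[np.ndarray]:
    """Transition matrices from a next-state map and discretized noise.

    ``next_state_fn(state, action, noise)`` maps a tuple of per-dimension
    state values and a tuple of noise realizations to the tuple of
    next-state values.  All noise combinations are enumerated, weighted by
    the product of their probabilities, and each outcome is projected onto
    the grid (independently per dimension, giving up to ``2**ndim``
    corners).  Intended for small test problems; the mallard case study
    builds its kernels with a vectorized equivalent.
    """
    shape = tuple(g.n for g in grids)
    states = list(itertools.product(*(range(g.n) for g in grids)))
    n_states = len(states)
    noise_combos = []
    for idx in itertools.product(*(range(n.nodes.size) for n in noises)):
        nodes = tuple(n.nodes[i] for n, i in zip(noises, idx))
        weight = float(np.prod([n.weights[i] for n, i in zip(noises, idx)]))
        noise_combos.append((nodes, weight))
    kernels = []
    for a in range(n_actions):
        T = np.zeros((n_states, n_states))
        for s, idx in enumerate(states):
            state = tuple(g.values[i] for g, i in zip(grids, idx))
            for noise, weight in noise_combos:
                nxt = next_state_fn(state, a, noise)
                if any(not np.isfinite(x) for x in np.atleast_1d(nxt)):
                    raise ValidationError(
                        f"next_state_fn returned a non-finite value at "
                        f"state={state}, action={a}, noise={noise}"
                    )
                splits = [project_to_grid(x, g) for x, g in zip(np.atleast_1d(nxt), grids)]
                for corner in itertools.product(*(range(len(ix)) for ix, _ in splits)):
                    j = np.ravel_multi_index(
                        tuple(splits[d][0][c] for d, c in enumerate(corner)), shape
                    )
                    mass = weight * float(
                        np.prod([splits[d][1][c] for d, c in enumerate(corner)])
                    )
                    T[s, j] += mass
        kernels.append(T)
    return kernels
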