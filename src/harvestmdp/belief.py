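"""Model state (weights over alternative models) and Bayesian updating.

Structural uncertainty is carried as a probability vector q over the K
alternative system models.  Policies are pre-solved on a regular lattice
over the weight simplex; at decision time a continuous belief is mapped
to the nearest lattice point (Euclidean distance).  After each observed
transition the belief itself is updated continuously by Bayes' rule with
model likelihoods read from the discretized kernels, so only the policy
lookup -- not the belief -- is ever snapped to the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .discretize import Grid1D, project_to_grid
from .errors import ValidationError

__all__ = [
    "ModelState",
    "BeliefGrid",
    "simplex_grid",
    "bayes_update",
    "transition_likelihood",
    "model_averaged",
    "nearest_belief",
]

WEIGHT_TOL = 1e-10


def _validate_weights(weights) -> np.ndarray:
    q = np.asarray(weights, dtype=float)
    if q.ndim != 1:
        raise ValidationError("weights must be a 1-d vector")
    if q.min() < -WEIGHT_TOL or q.max() > 1 + WEIGHT_TOL:
        raise ValidationError("weights must lie in [0, 1]")
    if abs(q.sum() - 1.0) > WEIGHT_TOL:
        raise ValidationError(f"weights sum to {q.sum()!r}, not 1")
    return q


@dataclass(frozen=True)
class ModelState:
    """A valid weight vector over the alternative models.

    For the mallard case study the order is (SaRs, SaRw, ScRs, ScRw).
    """

    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "weights", _validate_weights(self.weights))

    @property
    def k(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class BeliefGrid:
    """Regular lattice over the weight simplex."""

    points: np.ndarray  # (n_points, K)
    step: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def k(self) -> int:
        return self.points.shape[1]

    def index_of(self, weights, tol: float = 1e-9) -> int:
        """Index of the lattice point equal to ``weights`` (within ``tol``)."""
        q = _validate_weights(weights)
        d = np.abs(self.points - q).max(axis=1)
        i = int(d.argmin())
        if d[i] > tol:
            raise ValidationError("weights are not on the belief lattice")
        return i


def simplex_grid(k: int, step: float) -> BeliefGrid:
    """All weight vectors with entries that are multiples of ``step``.

    These are the compositions of ``1/step`` parts into ``k`` cells; for
    4 models at step 0.1 there are C(13, 3) = 286 lattice points.
    """
    inv = 1.0 / step
    if abs(inv - round(inv)) > 1e-9:
        raise ValidationError("1/step must be an integer")
    n = int(round(inv))

    def compositions(total, cells):
        if cells == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, cells - 1):
                yield (first, *rest)

    points = np.array(list(compositions(n, k)), dtype=float) * step
    return BeliefGrid(points=points, step=float(step))


def bayes_update(prior, likelihoods) -> np.ndarray:
    """Posterior weights proportional to prior times likelihood.

    Invariant to rescaling all likelihoods by a positive constant; a
    model with zero prior weight stays at zero.  Raises if the evidence
    has probability zero under every positively weighted model.
    """
    q = _validate_weights(prior if not isinstance(prior, ModelState) else prior.weights)
    lik = np.asarray(likelihoods, dtype=float)
    if lik.shape != q.shape:
        raise ValidationError("one likelihood per model required")
    if np.any(lik < 0):
        raise ValidationError("likelihoods must be non-negative")
    post = q * lik
    total = post.sum()
    if total <= 0:
        raise ValidationError(
            "observation has zero likelihood under every weighted model; "
            "posterior undefined"
        )
    return post / total


def transition_likelihood(
    kernel,
    previous_state: int,
    next_state=None,
    *,
    next_values: Sequence[float] | None = None,
    grids: Sequence[Grid1D] | None = None,
) -> float:
    """Model likelihood of an observed transition from a discrete kernel.

    ``kernel`` is one action's (S, S) matrix.  With an on-grid
    observation pass ``next_state`` (joint index); an off-grid
    observation (``next_values`` + ``grids``) is first projected onto
    the grid and the likelihood is the projection-weighted mixture of
    the bracketing entries.
    """
    row = kernel[previous_state]
    if sp.issparse(kernel):
        row = np.asarray(kernel[previous_state].todense()).ravel()
    if next_state is not None:
        return float(row[next_state])
    if next_values is None or grids is None:
        raise ValidationError("pass next_state, or next_values with grids")
    shape = tuple(g.n for g in grids)
    splits = [project_to_grid(v, g) for v, g in zip(next_values, grids)]
    total = 0.0
    idx0, w0 = splits[0]
    if len(splits) == 1:
        for i, wi in zip(idx0, w0):
            total += wi * row[i]
        return float(total)
    idx1, w1 = splits[1]
    for i, wi in zip(idx0, w0):
        for j, wj in zip(idx1, w1):
            total += wi * wj * row[np.ravel_multi_index((i, j), shape)]
    return float(total)


def model_averaged(operands: Sequence, weights) -> np.ndarray:
    """Convex combination of per-model kernels or utility tables."""
    q = _validate_weights(weights if not isinstance(weights, ModelState) else weights.weights)
    if len(operands) != q.size:
        raise ValidationError("one operand per model required")
    out = None
    for w, op in zip(q, operands):
        term = op * w
        out = term if out is None else out + term
    return out


def nearest_belief(weights, grid: BeliefGrid) -> int:
    """Index of the lattice point nearest in Euclidean distance.

    Ties break to the lowest index.  Vectorized: a (R, K) array of
    beliefs returns an (R,) index array.
    """
    q = np.asarray(weights if not isinstance(weights, ModelState) else weights.weights,
                   dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    if q2.shape[1] != grid.k:
        raise ValidationError("belief dimension does not match the lattice")
    d2 = ((q2[:, None, :] - grid.points[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return int(idx[0]) if single else idx
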