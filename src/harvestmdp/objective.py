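"""Devalued-harvest utility and the closed-season constraint.

The management objective maximizes undiscounted long-run mean harvest,
but devalues harvest whenever the action is expected to leave next
year's breeding population below a goal of 8.5 million:

    U(x, a) = E[ alpha(N') * H ],   alpha(N) = 1 if N >= 8.5 else N / 8.5

with the expectation taken jointly over process and harvest-rate noise
(alpha and H are correlated through the harvest-rate draw, so the
expectation of the product is used, not the product of expectations).

A closed season is off the table whenever the population *at the time of
the decision* is at least 4.75 million.  Post-survey that population is
observed; pre-survey the constraint applies to the projected population
E[N_t | x_{t-1}, q_{t-1}, a_{t-1}].  The boundary is inclusive: exactly
4.75 excludes the closed season.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .mallard import MallardTables

__all__ = [
    "ObjectiveParams",
    "devaluation",
    "utility_table",
    "expected_utility",
    "feasible_actions_post",
    "feasible_actions_pre",
]


@dataclass(frozen=True)
class ObjectiveParams:
    population_goal: float = 8.5  # millions; devaluation threshold
    closed_season_floor: float = 4.75  # millions; closed excluded at or above

    def __post_init__(self):
        if self.population_goal <= 0 or self.closed_season_floor <= 0:
            raise ValidationError("objective constants must be positive")


def devaluation(next_population, params: ObjectiveParams = ObjectiveParams()):
    """alpha(N): 1 at or above the goal, proportional below. Vectorized."""
    N = np.asarray(next_population, dtype=float)
    if np.any(N < 0):
        raise ValidationError("population must be non-negative")
    out = np.minimum(1.0, N / params.population_goal)
    return out if out.ndim else float(out)


def utility_table(tables: MallardTables, params: ObjectiveParams = ObjectiveParams()) -> np.ndarray:
    """Per-(state, action) expected utility E[alpha(N') H] for one model.

    Re-weights exactly the quadrature enumeration stored on the tables:
    alpha is evaluated at the continuous next-population node (before
    grid projection) and multiplied by the harvest at the same
    harvest-rate node.
    """
    wh = np.stack([hn.weights for hn in tables.harvest_noises])  # (A, nh)
    we = tables.eps_n_noise.weights  # (ne,)
    alpha = devaluation(tables.next_population_nodes, params)  # (A, S, nh, ne)
    # E over eps_N first, then the harvest-rate draw shared with H
    inner = np.einsum("ashe,e->ash", alpha, we)
    U = np.einsum("ash,ash,ah->sa", inner, tables.harvest_nodes, wh)
    return U


def expected_utility(
    tables: MallardTables,
    state: int,
    action: int,
    params: ObjectiveParams = ObjectiveParams(),
) -> float:
    """Scalar U(x, a) for one model at one grid state."""
    return float(utility_table(tables, params)[state, action])


def feasible_actions_post(
    population_values: np.ndarray,
    params: ObjectiveParams = ObjectiveParams(),
    n_actions: int = 4,
) -> np.ndarray:
    """(S, A) feasibility mask for post-survey decisions.

    Action 0 (closed) is infeasible wherever the observed population is at
    or above the closed-season floor; all other regulations are always
    available.
    """
    N = np.asarray(population_values, dtype=float)
    mask = np.ones((N.size, n_actions), dtype=bool)
    mask[:, 0] = N < params.closed_season_floor
    return mask


def feasible_actions_pre(
    expected_population: np.ndarray,
    params: ObjectiveParams = ObjectiveParams(),
    n_actions: int = 4,
) -> np.ndarray:
    """Feasibility mask over augmented (previous action, lagged state) pairs.

    ``expected_population[s, a_prev]`` is the (weight-averaged) projected
    current population given the lagged state and previous action.  The
    returned mask is ordered previous-action-major: augmented index
    ``a_prev * S + s``.
    """
    EN = np.asarray(expected_population, dtype=float)
    if EN.ndim != 2:
        raise ValidationError("expected_population must be (S, A_prev)")
    S, A_prev = EN.shape
    mask = np.ones((A_prev * S, n_actions), dtype=bool)
    mask[:, 0] = (EN.T.reshape(-1) < params.closed_season_floor)
    return mask
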