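"""Shared fixtures: small case studies and brute-force MDP oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from harvestmdp.case import build_case
from harvestmdp.config import GridConfig, RunConfig, SolverConfig
from harvestmdp.mdp import DiscreteMDP, policy_evaluation


@pytest.fixture(scope="session")
def coarse_case():
    """Mallard case study on an 18 x 8 state grid (step 1.0)."""
    cfg = RunConfig(
        population_grid=GridConfig(0.5, 17.5, 1.0),
        pond_grid=GridConfig(0.5, 7.5, 1.0),
    )
    return build_case(cfg)


@pytest.fixture(scope="session")
def tiny_case():
    """Mallard case study on a 9 x 4 state grid (step 2.0), 3 quadrature nodes."""
    cfg = RunConfig(
        population_grid=GridConfig(1.0, 17.0, 2.0),
        pond_grid=GridConfig(1.0, 7.0, 2.0),
        n_quadrature_nodes=3,
    )
    return build_case(cfg)


@pytest.fixture(scope="session")
def sim_case():
    """Case study on the simulation grid (step 0.5, 36 x 16 states)."""
    cfg = RunConfig(
        population_grid=GridConfig(0.5, 18.0, 0.5),
        pond_grid=GridConfig(0.5, 8.0, 0.5),
        solver=SolverConfig(tol=1e-6),
    )
    return build_case(cfg)


def enumerate_policies(mdp: DiscreteMDP):
    """All feasible stationary deterministic policies of a small MDP."""
    choices = [np.flatnonzero(mdp.feasible[s]) for s in range(mdp.n_states)]
    for combo in itertools.product(*choices):
        yield np.array(combo)


def brute_force_discounted(mdp: DiscreteMDP, discount: float):
    """Optimal value/policy by exhaustive policy enumeration + exact evaluation."""
    best_value = np.full(mdp.n_states, -np.inf)
    best_policy = None
    for policy in enumerate_policies(mdp):
        value = policy_evaluation(mdp, policy, "discounted", discount=discount)
        if value.sum() > best_value.sum():
            best_value, best_policy = value, policy
        best_value = np.maximum(best_value, value)
    return best_value, best_policy


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def brute_force_average_gain(mdp: DiscreteMDP) -> float:
    """Max over all stationary policies of the stationary-weighted reward."""
    best = -np.inf
    for policy in enumerate_policies(mdp):
        P_pi = np.vstack([np.asarray(mdp.transition[a][s]) for s, a in enumerate(policy)])
        r_pi = mdp.reward[np.arange(mdp.n_states), policy]
        pi = stationary_distribution(P_pi)
        best = max(best, float(pi @ r_pi))
    return best
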