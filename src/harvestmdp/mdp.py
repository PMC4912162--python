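"""Discrete-state, discrete-action Markov decision processes.

A :class:`DiscreteMDP` holds per-action transition matrices ``P(x'|x,a)``,
a per-(state, action) expected utility table ``U(x,a)``, and a boolean
feasibility mask used to express action constraints (e.g. a closed hunting
season being unavailable above a population floor).  Two stationary
optimality criteria are supported:

* the *discounted* criterion, ``V = max_a U + lam * P V`` with ``lam < 1``;
* the *average-reward* (ergodic) criterion, which maximizes the long-run
  mean utility per period and is the natural choice for sustainability
  objectives where a discount factor of 1 is required.

The average-reward solver is relative value iteration with an aperiodicity
(damping) transform so that periodic chains converge; on unichain problems
it returns a scalar gain and a relative value function.  If the gain turns
out to depend on the starting state (a multichain problem), the solver
issues :class:`~harvestmdp.errors.MultichainWarning` and reports per-state
gains instead of failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ConvergenceWarning, MultichainWarning, ValidationError

__all__ = [
    "DiscreteMDP",
    "SolutionResult",
    "solve_discounted",
    "solve_average_reward",
    "policy_evaluation",
    "bellman_residual",
]

#: row-stochasticity tolerance for transition matrices
ROW_SUM_TOL = 1e-10


def _as_matrix_list(transition) -> list:
    """Normalize transitions to a list of per-action (S, S) matrices.

    Accepts a 3-d array (A, S, S), or a sequence of dense/sparse matrices.
    """
    if isinstance(transition, np.ndarray) and transition.ndim == 3:
        return [transition[a] for a in range(transition.shape[0])]
    return list(transition)


@dataclass
class DiscreteMDP:
    """A finite MDP with optional per-state action constraints.

    Parameters
    ----------
    transition
        Sequence of per-action transition matrices, each ``(n_states,
        n_states)`` and row-stochastic (dense ndarray or scipy sparse).
        Rows of infeasible (state, action) pairs are ignored.
    reward
        Array ``(n_states, n_actions)`` of expected one-period utilities.
    feasible
        Boolean mask ``(n_states, n_actions)``; ``True`` marks an allowed
        action.  Defaults to everything allowed.  Infeasible actions are
        masked out of every maximization (never selected), keeping the
        matrices rectangular.
    """

    transition: Sequence
    reward: np.ndarray
    feasible: np.ndarray | None = None

    def __post_init__(self):
        self.transition = _as_matrix_list(self.transition)
        self.reward = np.asarray(self.reward, dtype=float)
        if self.reward.ndim != 2:
            raise ValidationError("reward must be a (n_states, n_actions) array")
        n_states, n_actions = self.reward.shape
        if len(self.transition) != n_actions:
            raise ValidationError(
                f"got {len(self.transition)} transition matrices for "
                f"{n_actions} actions"
            )
        for a, P in enumerate(self.transition):
            if P.shape != (n_states, n_states):
                raise ValidationError(
                    f"transition[{a}] has shape {P.shape}, expected "
                    f"{(n_states, n_states)}"
                )
        if self.feasible is None:
            self.feasible = np.ones((n_states, n_actions), dtype=bool)
        else:
            self.feasible = np.asarray(self.feasible, dtype=bool)
            if self.feasible.shape != (n_states, n_actions):
                raise ValidationError("feasible mask shape mismatch")
        self.validate()

    @property
    def n_states(self) -> int:
        return self.reward.shape[0]

    @property
    def n_actions(self) -> int:
        return self.reward.shape[1]

    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        """Check stochasticity over feasible rows and mask sanity."""
        if not self.feasible.any(axis=1).all():
            bad = int(np.flatnonzero(~self.feasible.any(axis=1))[0])
            raise ValidationError(f"state {bad} has an empty feasible action set")
        for a, P in enumerate(self.transition):
            rows = np.flatnonzero(self.feasible[:, a])
            if rows.size == 0:
                continue
            if sp.issparse(P):
                if P.data.size and (P.data.min() < -tol or P.data.max() > 1 + tol):
                    raise ValidationError(
                        f"transition[{a}] has probabilities outside [0, 1]"
                    )
                sums = np.asarray(P.sum(axis=1)).ravel()[rows]
            else:
                block = P[rows]
                if block.size and (block.min() < -tol or block.max() > 1 + tol):
                    raise ValidationError(
                        f"transition[{a}] has probabilities outside [0, 1]"
                    )
                sums = block.sum(axis=1)
            if sums.size and np.abs(sums - 1.0).max() > tol:
                s = int(rows[np.abs(sums - 1.0).argmax()])
                raise ValidationError(
                    f"transition[{a}] row {s} sums to {sums[np.abs(sums - 1.0).argmax()]:.12f}, "
                    "not 1"
                )


@dataclass
class SolutionResult:
    """Outcome of a policy optimization.

    ``gain`` is the scalar average reward (``None`` for the discounted
    criterion or when the problem is multichain, in which case
    ``state_gains`` carries the per-start-state gains).
    """

    policy: np.ndarray
    value: np.ndarray
    gain: float | None
    iterations: int
    converged: bool
    state_gains: np.ndarray | None = field(default=None, repr=False)


def _backup(mdp: DiscreteMDP, value: np.ndarray, discount: float) -> np.ndarray:
    """One Bellman backup: Q(x, a) = U(x, a) + discount * P_a v, masked."""
    q = np.empty_like(mdp.reward)
    for a, P in enumerate(mdp.transition):
        q[:, a] = mdp.reward[:, a] + discount * (P @ value)
    q[~mdp.feasible] = -np.inf
    return q


def bellman_residual(
    mdp: DiscreteMDP,
    value: np.ndarray,
    gain: float | np.ndarray | None = None,
    discount: float = 1.0,
) -> float:
    """Sup-norm residual of the (average-reward or discounted) optimality
    equation at ``value`` (and ``gain`` for the average criterion)."""
    w = _backup(mdp, value, discount).max(axis=1)
    if gain is None:
        return float(np.abs(w - value).max())
    return float(np.abs(w - value - gain).max())


def solve_discounted(
    mdp: DiscreteMDP,
    discount: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> SolutionResult:
    """Value iteration for the discounted criterion.

    Iterates until the Bellman residual is below ``tol`` in sup norm
    (guaranteed via the contraction bound), and returns the greedy policy.
    Ties in the argmax go to the lowest action index, i.e. the most
    conservative regulation when actions are ordered closed < restrictive
    < moderate < liberal.
    """
    if not 0 < discount < 1:
        raise ValidationError("discount must lie strictly in (0, 1)")
    v = np.zeros(mdp.n_states)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = _backup(mdp, v, discount)
        v_new = q.max(axis=1)
        # ||T v_new - v_new|| <= discount * ||v_new - v||
        if discount * np.abs(v_new - v).max() <= tol:
            v = v_new
            converged = True
            break
        v = v_new
    if not converged:
        warnings.warn(
            f"discounted value iteration did not converge in {max_iter} sweeps",
            ConvergenceWarning,
            stacklevel=2,
        )
    q = _backup(mdp, v, discount)
    policy = q.argmax(axis=1)
    return SolutionResult(policy=policy, value=q.max(axis=1), gain=None,
                          iterations=it, converged=converged)


def solve_average_reward(
    mdp: DiscreteMDP,
    tol: float = 1e-8,
    max_iter: int = 200_000,
    damping: float = 0.5,
    ref: int = 0,
) -> SolutionResult:
    """Relative value iteration for the average-reward criterion.

    The iterate is damped, ``v <- (1 - damping) v + damping (T v)``, an
    aperiodicity transform that leaves the gain and the optimal policy
    unchanged while guaranteeing convergence on unichain problems with
    periodic transition structure.  Convergence is declared on the span
    seminorm of the differential ``T v - v``, whose midpoint is the gain.

    If the differential stops changing while its span stays above ``tol``,
    the gain depends on the starting state: a :class:`MultichainWarning`
    is issued and the per-state gains are returned in ``state_gains``.
    """
    if not 0 < damping <= 1:
        raise ValidationError("damping must lie in (0, 1]")
    v = np.zeros(mdp.n_states)
    d_prev = None
    converged = False
    multichain = False
    it = 0
    d = np.zeros(mdp.n_states)
    for it in range(1, max_iter + 1):
        w = _backup(mdp, v, 1.0).max(axis=1)
        d = w - v
        span = d.max() - d.min()
        if span <= tol:
            converged = True
            break
        if d_prev is not None and np.abs(d - d_prev).max() <= tol * 1e-2:
            multichain = True
            break
        d_prev = d
        v = v + damping * d
        v -= v[ref]
    q = _backup(mdp, v, 1.0)
    policy = q.argmax(axis=1)
    if multichain:
        gains = np.unique(np.round(d, 9))
        warnings.warn(
            "average-reward gain differs across starting states "
            f"(per-class gains approximately {gains}); returning per-state gains",
            MultichainWarning,
            stacklevel=2,
        )
        return SolutionResult(policy=policy, value=v - v[ref], gain=None,
                              iterations=it, converged=False, state_gains=d.copy())
    if not converged:
        warnings.warn(
            f"relative value iteration did not converge in {max_iter} sweeps "
            f"(span {d.max() - d.min():.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    gain = 0.5 * (d.max() + d.min())
    return SolutionResult(policy=policy, value=v - v[ref], gain=float(gain),
                          iterations=it, converged=converged)


def _policy_matrices(mdp: DiscreteMDP, policy: np.ndarray):
    """Dense transition matrix and reward vector of a fixed policy."""
    policy = np.asarray(policy, dtype=int)
    if policy.shape != (mdp.n_states,):
        raise ValidationError("policy must assign one action per state")
    if not mdp.feasible[np.arange(mdp.n_states), policy].all():
        bad = int(np.flatnonzero(~mdp.feasible[np.arange(mdp.n_states), policy])[0])
        raise ValidationError(f"policy prescribes an infeasible action at state {bad}")
    rows = []
    for s, a in enumerate(policy):
        P = mdp.transition[a]
        row = P[s].toarray().ravel() if sp.issparse(P) else np.asarray(P[s])
        rows.append(row)
    P_pi = np.vstack(rows)
    r_pi = mdp.reward[np.arange(mdp.n_states), policy]
    return P_pi, r_pi


def policy_evaluation(
    mdp: DiscreteMDP,
    policy: np.ndarray,
    criterion: str = "discounted",
    discount: float | None = None,
    ref: int = 0,
):
    """Exact linear-solve evaluation of a fixed stationary policy.

    Returns the per-state value for the discounted criterion, or a
    ``(value, gain)`` pair for the average criterion (relative value
    normalized to 0 at the reference state).  A singular average-reward
    system (multichain policy) raises ``numpy.linalg.LinAlgError``.
    """
    P_pi, r_pi = _policy_matrices(mdp, policy)
    n = mdp.n_states
    if criterion == "discounted":
        if discount is None or not 0 < discount < 1:
            raise ValidationError("discounted evaluation needs discount in (0, 1)")
        return np.linalg.solve(np.eye(n) - discount * P_pi, r_pi)
    if criterion == "average":
        # (I - P) h + g * 1 = r, with h[ref] = 0 pinning the solution.
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = np.eye(n) - P_pi
        A[:n, n] = 1.0
        A[n, ref] = 1.0
        b = np.concatenate([r_pi, [0.0]])
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
            raise np.linalg.LinAlgError(
                "singular average-reward evaluation system; the policy's "
                "chain is likely multichain"
            ) from exc
        return sol[:n], float(sol[n])
    raise ValidationError(f"unknown criterion {criterion!r}")
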