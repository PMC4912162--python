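"""Assembly and solution of post- and pre-survey decision problems.

*Post-survey*: the action is chosen with the current (N, P) state in
hand.  For a belief q over the K models, the decision problem is an MDP
over the joint state grid with the q-averaged kernel and utility, solved
under the average-reward criterion (discount factor 1, consistent with
long-term sustainability).  This is the *passive* adaptive form: q is a
fixed parameter of each solve, updated outside the optimization as
observations accrue.

*Pre-survey*: the action must be chosen before the current state is
observed, so the decision state is augmented to (previous action, lagged
state).  The reward for choosing action a is the expectation of the
post-survey utility U_k(x_t, a) over the lagged one-step kernel
P_k(x_t | x_{t-1}, a_{t-1}), weight-averaged over models; the next
augmented state is (x_t, a) with x_t drawn from the same lagged kernel.
The closed-season constraint applies to the projected population.

Augmented states are ordered previous-action-major: index
``a_prev * S + s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence
import json

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .belief import BeliefGrid, model_averaged, nearest_belief
from .errors import ValidationError
from .mallard import REGULATIONS, MallardTables
from .mdp import DiscreteMDP, SolutionResult, solve_average_reward, solve_discounted
from .objective import (
    ObjectiveParams,
    feasible_actions_post,
    feasible_actions_pre,
    utility_table,
)

__all__ = [
    "PolicyTable",
    "PolicyFamily",
    "assemble_post",
    "assemble_pre",
    "solve_policy",
    "solve_belief_family",
]

POLICY_FORMAT_VERSION = 1


@dataclass
class PolicyTable:
    """A solved stationary policy plus the context needed to apply it.

    ``actions[s]`` (post mode) or ``actions[a_prev * S + s]`` (pre mode)
    is the prescribed regulation index.  ``belief`` records the model
    weights the solve was conditioned on (a vertex for single-model
    policies).
    """

    mode: str  # "post" | "pre"
    belief: tuple
    actions: np.ndarray
    gain: float | None
    criterion: str = "average"
    value: np.ndarray | None = field(default=None, repr=False)
    iterations: int = 0
    converged: bool = True
    n_values: np.ndarray | None = field(default=None, repr=False)
    p_values: np.ndarray | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: population, ponds[, previous action], regulation."""
        S = self.n_values.size * self.p_values.size
        n_col = np.repeat(self.n_values, self.p_values.size)
        p_col = np.tile(self.p_values, self.n_values.size)
        if self.mode == "pre":
            n_prev = self.actions.size // S
            frame = pd.DataFrame(
                {
                    "population": np.tile(n_col, n_prev),
                    "ponds": np.tile(p_col, n_prev),
                    "previous_action": np.repeat(
                        [REGULATIONS[a] for a in range(n_prev)], S
                    ),
                    "regulation": [REGULATIONS[a] for a in self.actions],
                }
            )
        else:
            frame = pd.DataFrame(
                {
                    "population": n_col,
                    "ponds": p_col,
                    "regulation": [REGULATIONS[a] for a in self.actions],
                }
            )
        return frame

    def save(self, path) -> None:
        """Write the policy as TSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        side = {
            "format_version": POLICY_FORMAT_VERSION,
            "mode": self.mode,
            "criterion": self.criterion,
            "belief": list(self.belief),
            "gain": self.gain,
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "n_values": list(map(float, self.n_values)),
            "p_values": list(map(float, self.p_values)),
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, path) -> "PolicyTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        actions = np.array([REGULATIONS.index(r) for r in frame["regulation"]])
        return cls(
            mode=side["mode"],
            belief=tuple(side["belief"]),
            actions=actions,
            gain=side["gain"],
            criterion=side["criterion"],
            iterations=side["iterations"],
            converged=side["converged"],
            n_values=np.array(side["n_values"]),
            p_values=np.array(side["p_values"]),
            metadata=side["metadata"],
        )


def _check_common_grid(tables: Sequence[MallardTables]) -> None:
    t0 = tables[0]
    for t in tables[1:]:
        if (
            t.n_grid.n != t0.n_grid.n
            or t.p_grid.n != t0.p_grid.n
            or np.abs(t.n_grid.values - t0.n_grid.values).max() > 1e-12
            or np.abs(t.p_grid.values - t0.p_grid.values).max() > 1e-12
        ):
            raise ValidationError("model tables were built on different grids")


def assemble_post(
    weights,
    tables: Sequence[MallardTables],
    utilities: Sequence[np.ndarray] | None = None,
    params: ObjectiveParams = ObjectiveParams(),
) -> DiscreteMDP:
    """Post-survey MDP over the joint (N, P) grid for one belief point."""
    _check_common_grid(tables)
    if utilities is None:
        utilities = [utility_table(t, params) for t in tables]
    A = tables[0].n_actions
    kernel = [
        model_averaged([t.kernel[a] for t in tables], weights) for a in range(A)
    ]
    reward = model_averaged(list(utilities), weights)
    n_vals, _ = tables[0].state_values()
    feasible = feasible_actions_post(n_vals, params, n_actions=A)
    return DiscreteMDP(transition=kernel, reward=reward, feasible=feasible)


def assemble_pre(
    weights,
    tables: Sequence[MallardTables],
    utilities: Sequence[np.ndarray] | None = None,
    params: ObjectiveParams = ObjectiveParams(),
    lag_kernels: Sequence[Sequence] | None = None,
    reward_averaging: str = "per-model",
) -> DiscreteMDP:
    """Pre-survey MDP over augmented (previous action, lagged state) pairs.

    ``lag_kernels`` overrides the per-model kernels used both as the
    lagged-state projection and the dynamics (one list of per-action
    matrices per model); by default the models' own kernels are used.
    Passing deterministic kernels here reduces the problem to the
    post-survey one (the lag then carries no uncertainty).

    ``reward_averaging`` selects how the model average enters the lagged
    expected utility.  ``"per-model"`` (default) couples each model's
    lag kernel with its own utility, ``sum_k q_k P_k U_k``: the reward
    is then the conditional expected utility given the realized state,
    with the model posterior implied by that state.  ``"mixture"``
    averages kernel and utility separately, ``(sum_k q_k P_k)(sum_k q_k
    U_k)``, which makes the pre-survey problem an exact information
    coarsening of the post-survey mixture problem (so its optimal gain
    can never exceed the post-survey gain).  The two coincide at vertex
    beliefs.  See the methods note for why the per-model form can beat
    the *passive* post-survey gain at mixed beliefs.
    """
    _check_common_grid(tables)
    if utilities is None:
        utilities = [utility_table(t, params) for t in tables]
    S = tables[0].n_states
    A = tables[0].n_actions
    if lag_kernels is None:
        lag_kernels = [t.kernel for t in tables]
    q = np.asarray(weights, dtype=float)

    # mixture kernel per previous action, densified for augmented assembly
    Pbar = []
    for ap in range(A):
        M = model_averaged([lk[ap] for lk in lag_kernels], q)
        Pbar.append(np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M))

    reward = np.zeros((A * S, A))
    if reward_averaging == "per-model":
        # sum_k q_k (P_k[a_prev] @ U_k)[s, a]
        for k, (lk, U) in enumerate(zip(lag_kernels, utilities)):
            for ap in range(A):
                block = lk[ap] @ U  # (S, A)
                reward[ap * S : (ap + 1) * S] += q[k] * np.asarray(block)
    elif reward_averaging == "mixture":
        Ubar = model_averaged(list(utilities), q)
        for ap in range(A):
            reward[ap * S : (ap + 1) * S] = Pbar[ap] @ Ubar
    else:
        raise ValidationError("reward_averaging must be 'per-model' or 'mixture'")

    # transition: (a_prev, s) --a--> (a, s') with s' ~ Pbar[a_prev][s]
    transition = []
    for a in range(A):
        M = np.zeros((A, S, A, S))
        for ap in range(A):
            M[ap, :, a, :] = Pbar[ap]
        transition.append(M.reshape(A * S, A * S))

    # projected population for the closed-season constraint
    EN = model_averaged([t.expected_next_population for t in tables], q)  # (S, A_prev)
    feasible = feasible_actions_pre(EN, params, n_actions=A)
    return DiscreteMDP(transition=transition, reward=reward, feasible=feasible)


def solve_policy(
    problem: DiscreteMDP,
    mode: str,
    belief,
    tables: Sequence[MallardTables] | None = None,
    criterion: str = "average",
    tol: float = 1e-8,
    max_iter: int = 200_000,
    discount: float | None = None,
    metadata: dict | None = None,
) -> PolicyTable:
    """Solve an assembled problem and wrap the result as a policy table."""
    if criterion == "average":
        res: SolutionResult = solve_average_reward(problem, tol=tol, max_iter=max_iter)
    elif criterion == "discounted":
        res = solve_discounted(problem, discount=discount, tol=tol, max_iter=max_iter)
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")
    n_vals = p_vals = None
    if tables is not None:
        n_vals = tables[0].n_grid.values
        p_vals = tables[0].p_grid.values
    return PolicyTable(
        mode=mode,
        belief=tuple(np.asarray(belief, dtype=float)),
        actions=res.policy,
        gain=res.gain,
        criterion=criterion,
        value=res.value,
        iterations=res.iterations,
        converged=res.converged,
        n_values=n_vals,
        p_values=p_vals,
        metadata=metadata or {},
    )


class PolicyFamily:
    """Lazily solved policies indexed by belief-lattice point.

    Each lattice point's problem is assembled and solved on first lookup
    and cached; ``solve_all`` forces the whole family.  Per-point solve
    failures are recorded (and the exception re-raised on lookup) rather
    than aborting sibling solves.
    """

    def __init__(
        self,
        belief_grid: BeliefGrid,
        mode: str,
        tables: Sequence[MallardTables],
        params: ObjectiveParams = ObjectiveParams(),
        tol: float = 1e-8,
        max_iter: int = 200_000,
        metadata: dict | None = None,
        reward_averaging: str = "per-model",
    ):
        if mode not in ("post", "pre"):
            raise ValidationError("mode must be 'post' or 'pre'")
        self.belief_grid = belief_grid
        self.mode = mode
        self.tables = list(tables)
        self.params = params
        self.tol = tol
        self.max_iter = max_iter
        self.reward_averaging = reward_averaging
        self.metadata = metadata or {}
        self._utilities = [utility_table(t, params) for t in self.tables]
        self._cache: dict[int, PolicyTable] = {}
        self.failures: dict[int, Exception] = {}

    def __len__(self) -> int:
        return self.belief_grid.n_points

    @property
    def n_solved(self) -> int:
        return len(self._cache)

    def get(self, index: int) -> PolicyTable:
        """Policy at lattice point ``index``, solving on first access."""
        if index in self._cache:
            return self._cache[index]
        if index in self.failures:
            raise self.failures[index]
        weights = self.belief_grid.points[index]
        try:
            if self.mode == "post":
                problem = assemble_post(weights, self.tables, self._utilities, self.params)
            else:
                problem = assemble_pre(
                    weights,
                    self.tables,
                    self._utilities,
                    self.params,
                    reward_averaging=self.reward_averaging,
                )
            table = solve_policy(
                problem,
                self.mode,
                weights,
                self.tables,
                tol=self.tol,
                max_iter=self.max_iter,
                metadata=dict(self.metadata, belief_index=index),
            )
        except Exception as exc:  # noqa: BLE001 - recorded, reported on lookup
            self.failures[index] = exc
            raise
        self._cache[index] = table
        return table

    def lookup(self, weights) -> PolicyTable:
        """Policy at the lattice point nearest a continuous belief."""
        return self.get(int(nearest_belief(weights, self.belief_grid)))

    def solve_all(self, progress: Callable[[int, int], None] | None = None):
        """Solve every lattice point; returns the list of policy tables."""
        out = []
        for i in range(len(self)):
            try:
                out.append(self.get(i))
            except Exception:  # noqa: BLE001
                out.append(None)
            if progress is not None:
                progress(i + 1, len(self))
        return out


def solve_belief_family(
    belief_grid: BeliefGrid,
    mode: str,
    tables: Sequence[MallardTables],
    params: ObjectiveParams = ObjectiveParams(),
    tol: float = 1e-8,
    lazy: bool = True,
    **kwargs,
) -> PolicyFamily:
    """Build a :class:`PolicyFamily`; eagerly solve it unless ``lazy``."""
    family = PolicyFamily(belief_grid, mode, tables, params, tol=tol, **kwargs)
    if not lazy:
        family.solve_all()
    return family
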