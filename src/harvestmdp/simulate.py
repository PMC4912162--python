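"""Monte Carlo evaluation of passively adaptive harvest policies.

Each replicate simulates the *discretized* dynamics of one designated
"true" model for a fixed horizon.  Every year the decision maker applies
the policy of the belief-lattice point nearest its current (continuous)
belief, harvest and the next state are realized from sampled quadrature
nodes, and the belief is updated by Bayes' rule from the likelihood of
the observed grid transition under each of the K kernels.  Beliefs are
never snapped to the lattice between years -- only the policy lookup is
discretized -- which keeps simulated beliefs from prematurely reaching
certainty.

Sequencing differs by mode.  Post-survey: the current state is observed,
the belief incorporates it, then the action is chosen.  Pre-survey: the
action is chosen from the *lagged* state, the previous action, and the
belief updated only through that lagged state; the current state is
observed afterwards.

Randomness: one child seed per replicate is spawned from the master
seed, and each replicate-year consumes a fixed block of uniform draws in
a fixed order (harvest-rate node, eps_N node, eps_P node, the two
projection splits).  Runs with the same master seed therefore share
common random numbers across modes and true models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .belief import nearest_belief
from .errors import ValidationError
from .mallard import MODEL_LABELS, REGULATIONS, MallardTables
from .policy import PolicyFamily

__all__ = ["SimulationConfig", "SimulationSummary", "run_simulation"]


@dataclass
class SimulationConfig:
    """Study conditions for a simulation run.

    Defaults are the published study conditions: 10,000 replicates of 50
    years, initial population 6 million and ponds 4 million, initial
    belief (0.1, 0.5, 0.1, 0.3), and (pre-survey mode) an initial
    previous action of liberal.
    """

    true_model: str = "SaRw"
    replicates: int = 10_000
    horizon: int = 50
    initial_population: float = 6.0
    initial_ponds: float = 4.0
    initial_action: str = "liberal"
    initial_belief: tuple = (0.1, 0.5, 0.1, 0.3)
    seed: int = 0
    mode: str = "post"
    keep_trajectories: bool = False

    def __post_init__(self):
        if self.mode not in ("post", "pre"):
            raise ValidationError("mode must be 'post' or 'pre'")
        if self.replicates < 1 or self.horizon < 1:
            raise ValidationError("replicates and horizon must be positive")
        if self.initial_action not in REGULATIONS:
            raise ValidationError(f"unknown initial action {self.initial_action!r}")


@dataclass
class SimulationSummary:
    """Per-year summaries across replicates (year 1 is the first decision)."""

    mode: str
    true_model: str
    replicates: int
    mean_population: np.ndarray
    sd_population: np.ndarray
    mean_harvest: np.ndarray
    sd_harvest: np.ndarray
    action_frequencies: np.ndarray  # (T, A)
    mean_weights: np.ndarray  # (T, K), decision-time beliefs
    model_labels: tuple = MODEL_LABELS
    trajectories: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        T = self.mean_population.size
        data = {
            "year": np.arange(1, T + 1),
            "mean_population": self.mean_population,
            "sd_population": self.sd_population,
            "mean_harvest": self.mean_harvest,
            "sd_harvest": self.sd_harvest,
        }
        for a, name in enumerate(REGULATIONS):
            data[f"freq_{name}"] = self.action_frequencies[:, a]
        for k, label in enumerate(self.model_labels):
            data[f"weight_{label}"] = self.mean_weights[:, k]
        return pd.DataFrame(data)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def first_year_weight_reaches(self, model: str | int, threshold: float) -> int | None:
        """First year the replicate-mean weight on a model meets a threshold."""
        k = self.model_labels.index(model) if isinstance(model, str) else int(model)
        hit = np.flatnonzero(self.mean_weights[:, k] >= threshold)
        return int(hit[0]) + 1 if hit.size else None


def _dense_kernels(tables: Sequence[MallardTables]) -> np.ndarray:
    """(K, A, S, S) dense kernel stack for vectorized likelihood lookups."""
    K = len(tables)
    A = tables[0].n_actions
    S = tables[0].n_states
    out = np.empty((K, A, S, S))
    for k, t in enumerate(tables):
        for a, P in enumerate(t.kernel):
            out[k, a] = np.asarray(P.todense()) if sp.issparse(P) else np.asarray(P)
    return out


def _sample_index(cum_weights: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of node indices, vectorized over replicates."""
    return np.searchsorted(cum_weights, u, side="right").clip(0, cum_weights.size - 1)


def run_simulation(
    config: SimulationConfig,
    family: PolicyFamily,
    tables: Sequence[MallardTables],
) -> SimulationSummary:
    """Simulate the true model under a nearest-belief adaptive policy.

    ``tables`` holds the kernels of *all* K alternative models (in belief
    order); ``config.true_model`` selects the data-generating one.
    ``family`` must match ``config.mode``.
    """
    if family.mode != config.mode:
        raise ValidationError(
            f"policy family is {family.mode!r} but simulation mode is {config.mode!r}"
        )
    labels = [t.model.label for t in tables]
    if labels != list(MODEL_LABELS):
        raise ValidationError(f"tables must be in canonical model order {MODEL_LABELS}")
    k_true = labels.index(config.true_model)
    true = tables[k_true]
    n_grid, p_grid = true.n_grid, true.p_grid
    S, A = true.n_states, true.n_actions
    nP = p_grid.n
    R_reps, T = config.replicates, config.horizon

    kernels = _dense_kernels(tables)  # (K, A, S, S)
    q0 = np.asarray(config.initial_belief, dtype=float)
    family.belief_grid.index_of(q0)  # study condition: initial belief on the lattice
    s0 = true.state_index(config.initial_population, config.initial_ponds)
    a_init = REGULATIONS.index(config.initial_action)

    # quadrature-node index distributions (weights shared across actions)
    cum_h = np.cumsum(true.harvest_noises[0].weights)
    cum_en = np.cumsum(true.eps_n_noise.weights)
    cum_ep = np.cumsum(true.eps_p_noise.weights)

    # per-replicate uniform draw blocks: (R, T + 1, 5); row 0 initializes
    # the pre-survey first state, rows 1..T drive years 1..T in both modes
    children = np.random.SeedSequence(config.seed).spawn(R_reps)
    uniforms = np.stack(
        [np.random.Generator(np.random.PCG64(c)).random((T + 1, 5)) for c in children]
    )

    def transition(s, a, u):
        """Sampled grid transition + realized harvest for all replicates."""
        hi = _sample_index(cum_h, u[:, 0])
        ei = _sample_index(cum_en, u[:, 1])
        pi = _sample_index(cum_ep, u[:, 2])
        n_next = true.next_population_nodes[a, s, hi, ei]
        p_next = true.pond_next_nodes[s % nP, pi]
        lo_n = np.clip(((n_next - n_grid.lower) // n_grid.step).astype(int), 0, n_grid.n - 2)
        w_n = np.clip((n_next - n_grid.values[lo_n]) / n_grid.step, 0.0, 1.0)
        i_n = lo_n + (u[:, 3] < w_n)  # w_n is the mass on the upper bracketing node
        lo_p = np.clip(((p_next - p_grid.lower) // p_grid.step).astype(int), 0, p_grid.n - 2)
        w_p = np.clip((p_next - p_grid.values[lo_p]) / p_grid.step, 0.0, 1.0)
        i_p = lo_p + (u[:, 4] < w_p)
        harvest = true.harvest_nodes[a, s, hi]
        return i_n * nP + i_p, harvest

    def actions_for(beliefs, lookup_state):
        """Nearest-lattice policy lookup, solving lattice points on demand."""
        idx = np.atleast_1d(nearest_belief(beliefs, family.belief_grid))
        acts = np.empty(lookup_state.size, dtype=int)
        for b in np.unique(idx):
            acts[idx == b] = family.get(int(b)).actions[lookup_state[idx == b]]
        return acts

    n_vals, _ = true.state_values()
    q = np.tile(q0, (R_reps, 1))
    mean_N = np.empty(T); sd_N = np.empty(T)
    mean_H = np.empty(T); sd_H = np.empty(T)
    freq = np.zeros((T, A))
    mean_w = np.empty((T, len(tables)))
    traj_beliefs = np.empty((R_reps, T, len(tables))) if config.keep_trajectories else None
    traj_states = np.empty((R_reps, T), dtype=int) if config.keep_trajectories else None

    if config.mode == "post":
        s = np.full(R_reps, s0)
        s_prev = None
        a_prev = None
        for t in range(T):
            if t > 0:
                lik = kernels[:, a_prev, s_prev, s].T  # (R, K)
                q = q * lik
                tot = q.sum(axis=1)
                if np.any(tot <= 0):
                    raise ValidationError("observed transition impossible under all models")
                q /= tot[:, None]
            mean_w[t] = q.mean(axis=0)
            a = actions_for(q, s)
            s_next, H = transition(s, a, uniforms[:, t + 1])
            mean_N[t] = n_vals[s].mean(); sd_N[t] = n_vals[s].std()
            mean_H[t] = H.mean(); sd_H[t] = H.std()
            freq[t] = np.bincount(a, minlength=A) / R_reps
            if config.keep_trajectories:
                traj_beliefs[:, t] = q
                traj_states[:, t] = s
            s_prev, a_prev, s = s, a, s_next
    else:
        s_lag = np.full(R_reps, s0)
        a_lag = np.full(R_reps, a_init)
        # first current state realized from the lagged initial conditions
        s_cur, _ = transition(s_lag, a_lag, uniforms[:, 0])
        for t in range(T):
            mean_w[t] = q.mean(axis=0)
            a = actions_for(q, a_lag * S + s_lag)
            # belief catches up with the newly observed current state
            lik = kernels[:, a_lag, s_lag, s_cur].T
            q_new = q * lik
            tot = q_new.sum(axis=1)
            if np.any(tot <= 0):
                raise ValidationError("observed transition impossible under all models")
            q_new /= tot[:, None]
            s_next, H = transition(s_cur, a, uniforms[:, t + 1])
            mean_N[t] = n_vals[s_cur].mean(); sd_N[t] = n_vals[s_cur].std()
            mean_H[t] = H.mean(); sd_H[t] = H.std()
            freq[t] = np.bincount(a, minlength=A) / R_reps
            if config.keep_trajectories:
                traj_beliefs[:, t] = q
                traj_states[:, t] = s_cur
            s_lag, a_lag, q, s_cur = s_cur, a, q_new, s_next

    trajectories = {}
    if config.keep_trajectories:
        trajectories = {"beliefs": traj_beliefs, "states": traj_states}
    return SimulationSummary(
        mode=config.mode,
        true_model=config.true_model,
        replicates=R_reps,
        mean_population=mean_N,
        sd_population=sd_N,
        mean_harvest=mean_H,
        sd_harvest=sd_H,
        action_frequencies=freq,
        mean_weights=mean_w,
        trajectories=trajectories,
    )


def plot_summary(summary: SimulationSummary, path=None):
    """Minimal four-panel view of a simulation summary (optional helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = summary.to_frame()
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    years = frame["year"]
    axes[0, 0].plot(years, frame["mean_population"])
    axes[0, 0].fill_between(
        years,
        frame["mean_population"] - frame["sd_population"],
        frame["mean_population"] + frame["sd_population"],
        alpha=0.3,
    )
    axes[0, 0].set_ylabel("population (millions)")
    axes[0, 1].plot(years, frame["mean_harvest"])
    axes[0, 1].set_ylabel("harvest (millions)")
    for name in REGULATIONS:
        axes[1, 0].plot(years, frame[f"freq_{name}"], label=name)
    axes[1, 0].set_ylabel("action frequency")
    axes[1, 0].legend(fontsize=7)
    for label in summary.model_labels:
        axes[1, 1].plot(years, frame[f"weight_{label}"], label=label)
    axes[1, 1].set_ylabel("mean model weight")
    axes[1, 1].legend(fontsize=7)
    for ax in axes[1]:
        ax.set_xlabel("year")
    fig.suptitle(f"{summary.mode}-survey policy, true model {summary.true_model}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
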