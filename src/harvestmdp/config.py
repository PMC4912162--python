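"""Run configuration, fixture generation, and file round-tripping.

A :class:`RunConfig` collects every number the case study needs -- grid
bounds and steps, quadrature node counts, biological constants, the
regulation set, objective constants, the belief-lattice step, and solver
settings.  Defaults are the published 2015 operational values; an empty
config file therefore reproduces the published setup.  Note the source
text's grid sentence is internally inconsistent (the stated interval
0.5-18 yields 141 points, the stated count is 144); the defaults honor
the printed *counts* (144 x 64 at step 0.125, hence a lower bound of
0.125), and both bounds are configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .discretize import Grid1D, build_grid
from .errors import ValidationError
from .mallard import BiologicalConstants, RegulationSet
from .mdp import DiscreteMDP
from .objective import ObjectiveParams

__all__ = [
    "GridConfig",
    "SolverConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "generate_fixture_mdp",
    "mdp_to_json",
    "mdp_from_json",
]

FIXTURE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridConfig:
    lower: float
    upper: float
    step: float

    def build(self) -> Grid1D:
        return build_grid(self.lower, self.upper, self.step)


@dataclass(frozen=True)
class SolverConfig:
    tol: float = 1e-8
    max_iter: int = 200_000
    damping: float = 0.5

    def __post_init__(self):
        if self.tol <= 0:
            raise ValidationError("tol must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of the case study; defaults are the published values."""

    population_grid: GridConfig = GridConfig(lower=0.125, upper=18.0, step=0.125)
    pond_grid: GridConfig = GridConfig(lower=0.125, upper=8.0, step=0.125)
    n_quadrature_nodes: int = 5
    constants: BiologicalConstants = BiologicalConstants()
    regulations: RegulationSet = RegulationSet()
    objective: ObjectiveParams = ObjectiveParams()
    belief_step: float = 0.1
    solver: SolverConfig = SolverConfig()
    seed: int = 0

    def __post_init__(self):
        if self.n_quadrature_nodes < 1:
            raise ValidationError("n_quadrature_nodes must be at least 1")
        inv = 1.0 / self.belief_step
        if abs(inv - round(inv)) > 1e-9:
            raise ValidationError("1/belief_step must be an integer")


_SECTION_TYPES = {
    "population_grid": GridConfig,
    "pond_grid": GridConfig,
    "constants": BiologicalConstants,
    "regulations": RegulationSet,
    "objective": ObjectiveParams,
    "solver": SolverConfig,
}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path=None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the published defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValidationError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Short stable digest identifying a configuration (grid-mixing guard)."""
    payload = json.dumps(asdict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_fixture_mdp(n_states: int, n_actions: int, seed: int) -> DiscreteMDP:
    """Small random MDP for oracle testing (Dirichlet rows, uniform rewards)."""
    if n_states > 8:
        raise ValidationError("fixture MDPs are capped at 8 states for enumeration oracles")
    rng = np.random.default_rng(seed)
    transition = rng.dirichlet(np.ones(n_states), size=(n_actions, n_states))
    reward = rng.uniform(0.0, 1.0, size=(n_states, n_actions))
    return DiscreteMDP(transition=transition, reward=reward)


def mdp_to_json(mdp: DiscreteMDP, path=None) -> str:
    """Serialize a (dense) MDP to the documented JSON fixture layout."""
    doc = {
        "format_version": FIXTURE_FORMAT_VERSION,
        "n_states": mdp.n_states,
        "n_actions": mdp.n_actions,
        "transition": [np.asarray(P).ravel().tolist() for P in mdp.transition],
        "reward": np.asarray(mdp.reward).ravel().tolist(),
        "feasible": np.asarray(mdp.feasible).ravel().astype(int).tolist(),
    }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def mdp_from_json(source) -> DiscreteMDP:
    """Inverse of :func:`mdp_to_json`; accepts a path or a JSON string."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = json.loads(text)
    S, A = doc["n_states"], doc["n_actions"]
    transition = [np.array(rows).reshape(S, S) for rows in doc["transition"]]
    reward = np.array(doc["reward"]).reshape(S, A)
    feasible = np.array(doc["feasible"]).reshape(S, A).astype(bool)
    return DiscreteMDP(transition=transition, reward=reward, feasible=feasible)
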