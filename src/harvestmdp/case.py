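"""Convenience assembly of the fully parameterized mallard case study.

``build_case`` turns a :class:`~harvestmdp.config.RunConfig` into a
:class:`CaseStudy` holding the grids, the four model kernels (with their
expectation tables), per-model utility tables, and the belief lattice --
everything the policy and simulation layers consume.  The config hash is
threaded into policy metadata so policies and simulations can never
silently mix grids.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .belief import BeliefGrid, simplex_grid
from .config import RunConfig, config_hash
from .discretize import Grid1D
from .mallard import MallardTables, build_model_kernel, four_models
from .objective import utility_table
from .policy import PolicyFamily

__all__ = ["CaseStudy", "build_case"]

log = logging.getLogger(__name__)


@dataclass
class CaseStudy:
    config: RunConfig
    n_grid: Grid1D
    p_grid: Grid1D
    tables: list  # one MallardTables per model, canonical order
    utilities: list  # one (S, A) array per model
    belief_grid: BeliefGrid
    hash: str = ""
    _families: dict = field(default_factory=dict, repr=False)

    @property
    def n_states(self) -> int:
        return self.n_grid.n * self.p_grid.n

    def family(self, mode: str) -> PolicyFamily:
        """Lazily constructed (and lazily solved) policy family per mode."""
        if mode not in self._families:
            self._families[mode] = PolicyFamily(
                self.belief_grid,
                mode,
                self.tables,
                self.config.objective,
                tol=self.config.solver.tol,
                max_iter=self.config.solver.max_iter,
                metadata={"config_hash": self.hash},
            )
        return self._families[mode]


def build_case(config: RunConfig | None = None, sparse: bool | None = None) -> CaseStudy:
    """Build grids, kernels, utilities and the belief lattice from a config."""
    config = config or RunConfig()
    n_grid = config.population_grid.build()
    p_grid = config.pond_grid.build()
    models = four_models()
    tables: list[MallardTables] = []
    for model in models:
        t0 = time.perf_counter()
        tab = build_model_kernel(
            model,
            config.constants,
            config.regulations,
            n_grid,
            p_grid,
            n_nodes=config.n_quadrature_nodes,
            sparse=sparse,
        )
        log.info(
            "kernel %s: %d states x %d actions in %.2f s",
            model.label, tab.n_states, tab.n_actions, time.perf_counter() - t0,
        )
        tables.append(tab)
    utilities = [utility_table(t, config.objective) for t in tables]
    belief_grid = simplex_grid(len(models), config.belief_step)
    return CaseStudy(
        config=config,
        n_grid=n_grid,
        p_grid=p_grid,
        tables=tables,
        utilities=utilities,
        belief_grid=belief_grid,
        hash=config_hash(config),
    )
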