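"""Mid-continent mallard population dynamics and harvest.

Four alternative annual population models are formed by crossing two
survival hypotheses (harvest mortality additive to, or compensated by,
natural mortality) with two reproduction hypotheses (strong or weak
density dependence of the fall age ratio).  The models share a balance
equation for breeding population size ``N`` (millions):

    N' = g_S * N * { m*S_AM + (1-m)*[S_AF + g_R*R*(S_JF + S_JM*phi)] } * exp(eps_N)

where ``m`` is the male proportion, ``S_..`` are cohort annual survivals,
``R`` the fall age ratio, ``phi`` the female:male summer survival ratio,
``g_S, g_R`` bias corrections, and ``eps_N ~ N(0, 0.0184)``.  Pond counts
``P`` follow a model-free AR(1), ``P' = max(0, 2.2127 + 0.3420 P + eps_P)``
with ``eps_P ~ N(0, 1.257)``.

Harvest is only partially controllable: each regulatory alternative
(closed, restrictive, moderate, liberal) induces a normal distribution of
the adult-male harvest rate; other cohorts scale by fixed historic ratios.
The total kill rate ``K`` inflates the retrieved-harvest rate by a 20%
crippling loss.

:func:`build_model_kernel` turns one model into per-regulation transition
matrices over the (N, P) grid plus expected-harvest and expected-next-
population tables, by enumerating the quadrature nodes of the three noise
sources (harvest rate, eps_N, eps_P) and projecting each outcome onto the
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .discretize import DiscreteNoise, Grid1D, gauss_hermite, projection_split
from .errors import ValidationError

__all__ = [
    "REGULATIONS",
    "COHORTS",
    "SystemState",
    "SurvivalParams",
    "ReproductionParams",
    "BiologicalConstants",
    "RegulationSet",
    "ModelSpec",
    "MallardTables",
    "ADDITIVE_SURVIVAL",
    "COMPENSATORY_SURVIVAL",
    "STRONG_REPRODUCTION",
    "WEAK_REPRODUCTION",
    "MODEL_LABELS",
    "four_models",
    "annual_survival",
    "reproduction_rate",
    "kill_rate",
    "population_transition",
    "pond_transition",
    "expected_total_harvest",
    "harvest_given_rate",
    "build_model_kernel",
]

#: regulatory alternatives in increasing order of liberality
REGULATIONS = ("closed", "restrictive", "moderate", "liberal")
#: cohort order used throughout: adult male, adult female, young male, young female
COHORTS = ("adult_male", "adult_female", "young_male", "young_female")


@dataclass(frozen=True)
class SystemState:
    """Breeding population (millions of birds) and May ponds (millions)."""

    population: float
    ponds: float

    def __post_init__(self):
        if self.population < 0 or self.ponds < 0:
            raise ValidationError("population and ponds must be non-negative")


@dataclass(frozen=True)
class SurvivalParams:
    """Sex-specific survival in the absence of harvest, and the hypothesis form."""

    s0_male: float
    s0_female: float
    form: str  # "additive" | "compensatory"

    def __post_init__(self):
        if not (0 < self.s0_male < 1 and 0 < self.s0_female < 1):
            raise ValidationError("baseline survivals must lie in (0, 1)")
        if self.form not in ("additive", "compensatory"):
            raise ValidationError(f"unknown survival form {self.form!r}")


@dataclass(frozen=True)
class ReproductionParams:
    """Linear fall-age-ratio model R = max(0, intercept + pond_coef*P + pop_coef*N)."""

    intercept: float
    pond_coef: float
    pop_coef: float  # per million birds; negative (density dependence)

    def __post_init__(self):
        if self.pop_coef > 0:
            raise ValidationError("pop_coef must be non-positive (density dependence)")


# Printed parameter estimates for the two survival and two reproduction
# hypotheses (2015 operational values).
ADDITIVE_SURVIVAL = SurvivalParams(s0_male=0.7896, s0_female=0.6886, form="additive")
COMPENSATORY_SURVIVAL = SurvivalParams(s0_male=0.6467, s0_female=0.5965, form="compensatory")
STRONG_REPRODUCTION = ReproductionParams(intercept=1.1390, pond_coef=0.1376, pop_coef=-0.1131)
WEAK_REPRODUCTION = ReproductionParams(intercept=0.7166, pond_coef=0.1083, pop_coef=-0.0373)


@dataclass(frozen=True)
class BiologicalConstants:
    """Shared constants of the balance equation and the pond AR(1).

    ``male_proportion``, ``summer_survival_ratio`` and the two bias
    corrections are operational values that live in the management
    protocol's supplementary material rather than the main text; the
    defaults below are documented placeholders and every one of them is
    configurable.
    """

    male_proportion: float = 0.55
    summer_survival_ratio: float = 0.9  # phi_F / phi_M over summer
    bias_correction_survival: float = 1.0
    bias_correction_reproduction: float = 1.0
    process_error_variance_N: float = 0.0184
    pond_intercept: float = 2.2127
    pond_slope: float = 0.3420
    process_error_variance_P: float = 1.257
    crippling_loss: float = 0.20
    crippling_convention: str = "divide"  # K = h / (1 - c); "multiply": K = h * (1 + c)

    def __post_init__(self):
        if not 0 < self.male_proportion < 1:
            raise ValidationError("male_proportion must lie in (0, 1)")
        if self.process_error_variance_N <= 0 or self.process_error_variance_P <= 0:
            raise ValidationError("process error variances must be positive")
        if not 0 <= self.crippling_loss < 1:
            raise ValidationError("crippling_loss must lie in [0, 1)")
        if self.crippling_convention not in ("divide", "multiply"):
            raise ValidationError("crippling_convention must be 'divide' or 'multiply'")


@dataclass(frozen=True)
class RegulationSet:
    """Adult-male harvest-rate distributions per regulation + cohort ratios."""

    means: tuple = (0.0088, 0.0552, 0.0977, 0.1139)
    sds: tuple = (0.0020, 0.0129, 0.0215, 0.0179)
    ratio_young_male: float = 1.5407
    ratio_adult_female: float = 0.7191
    ratio_young_female: float = 1.1175

    def __post_init__(self):
        if len(self.means) != len(self.sds):
            raise ValidationError("means and sds must have equal length")
        if np.any(np.diff(self.means) <= 0):
            raise ValidationError("harvest-rate means must increase from closed to liberal")
        if min(self.ratio_young_male, self.ratio_adult_female, self.ratio_young_female) <= 0:
            raise ValidationError("cohort ratios must be positive")

    @property
    def n_regulations(self) -> int:
        return len(self.means)

    def cohort_ratios(self) -> np.ndarray:
        """Ratios in :data:`COHORTS` order (adult male is the reference, 1)."""
        return np.array(
            [1.0, self.ratio_adult_female, self.ratio_young_male, self.ratio_young_female]
        )

    def harvest_noise(self, regulation: int | str, n_nodes: int = 5) -> DiscreteNoise:
        """Discretized adult-male harvest-rate distribution for a regulation.

        Nodes are clamped at zero (a normal tail can dip below zero for
        the closed season); the clamp changes node values, not weights.
        """
        a = REGULATIONS.index(regulation) if isinstance(regulation, str) else int(regulation)
        if not 0 <= a < self.n_regulations:
            raise ValidationError(f"unknown regulation {regulation!r}")
        noise = gauss_hermite(self.means[a], self.sds[a] ** 2, n_nodes)
        return DiscreteNoise(nodes=np.maximum(noise.nodes, 0.0), weights=noise.weights)


@dataclass(frozen=True)
class ModelSpec:
    """One of the four alternative population models."""

    survival: SurvivalParams
    reproduction: ReproductionParams
    label: str

    def __post_init__(self):
        expected = (
            ("Sa" if self.survival.form == "additive" else "Sc")
            + ("Rs" if self.reproduction.pop_coef < WEAK_REPRODUCTION.pop_coef else "Rw")
        )
        if self.label != expected:
            raise ValidationError(
                f"label {self.label!r} inconsistent with components (expected {expected!r})"
            )


def four_models() -> tuple[ModelSpec, ModelSpec, ModelSpec, ModelSpec]:
    """The alternative models in canonical weight order (SaRs, SaRw, ScRs, ScRw)."""
    return (
        ModelSpec(ADDITIVE_SURVIVAL, STRONG_REPRODUCTION, "SaRs"),
        ModelSpec(ADDITIVE_SURVIVAL, WEAK_REPRODUCTION, "SaRw"),
        ModelSpec(COMPENSATORY_SURVIVAL, STRONG_REPRODUCTION, "ScRs"),
        ModelSpec(COMPENSATORY_SURVIVAL, WEAK_REPRODUCTION, "ScRw"),
    )


MODEL_LABELS = tuple(m.label for m in four_models())


def annual_survival(params: SurvivalParams, sex: str, kill_rate):
    """Annual survival under the additive or compensatory hypothesis.

    Additive: ``s0 * (1 - K)``.  Compensatory: density-dependent
    non-hunting mortality absorbs harvest up to the threshold ``1 - s0``,
    so survival is ``s0`` for ``K <= 1 - s0`` and ``1 - K`` beyond it.
    Vectorized over ``kill_rate``.
    """
    K = np.asarray(kill_rate, dtype=float)
    if np.any((K < 0) | (K > 1)):
        raise ValidationError("kill rate must lie in [0, 1]")
    s0 = {"male": params.s0_male, "female": params.s0_female}.get(sex)
    if s0 is None:
        raise ValidationError(f"unknown sex {sex!r}")
    if params.form == "additive":
        out = s0 * (1.0 - K)
    else:
        out = np.where(K <= 1.0 - s0, s0, 1.0 - K)
    return out if out.ndim else float(out)


def reproduction_rate(params: ReproductionParams, ponds, population):
    """Fall age ratio from the linear model, clamped at zero."""
    P = np.asarray(ponds, dtype=float)
    N = np.asarray(population, dtype=float)
    out = np.maximum(0.0, params.intercept + params.pond_coef * P + params.pop_coef * N)
    return out if out.ndim else float(out)


def kill_rate(
    harvest_rate,
    cohort_ratio: float = 1.0,
    crippling_loss: float = 0.20,
    convention: str = "divide",
):
    """Total kill rate from a retrieved (adult-male) harvest rate.

    The cohort's harvest rate is ``ratio * h``; unretrieved kill inflates
    it by the crippling loss ``c``: ``K = ratio*h / (1 - c)`` under the
    default convention, or ``ratio*h * (1 + c)`` under the alternative.
    Capped at 1.
    """
    h = np.asarray(harvest_rate, dtype=float)
    if np.any(h < 0):
        raise ValidationError("harvest rate must be non-negative")
    if convention == "divide":
        K = cohort_ratio * h / (1.0 - crippling_loss)
    elif convention == "multiply":
        K = cohort_ratio * h * (1.0 + crippling_loss)
    else:
        raise ValidationError("convention must be 'divide' or 'multiply'")
    out = np.minimum(K, 1.0)
    return out if out.ndim else float(out)


def _cohort_kill_rates(regs: RegulationSet, consts: BiologicalConstants, harvest_rate):
    """Kill rates for all four cohorts given adult-male harvest rate(s).

    Returns an array with a leading cohort axis in :data:`COHORTS` order.
    """
    h = np.asarray(harvest_rate, dtype=float)
    return np.stack(
        [
            kill_rate(h, r, consts.crippling_loss, consts.crippling_convention)
            for r in regs.cohort_ratios()
        ]
    )


def _survivals(model: ModelSpec, kill_rates: np.ndarray) -> np.ndarray:
    """Cohort survivals (COHORTS order) from cohort kill rates (same order)."""
    sexes = ("male", "female", "male", "female")
    return np.stack(
        [annual_survival(model.survival, sex, np.asarray(K))
         for sex, K in zip(sexes, kill_rates)]
    )


def population_transition(
    model: ModelSpec,
    consts: BiologicalConstants,
    state: SystemState,
    kill_rates: Sequence[float],
    eps_n: float = 0.0,
) -> float:
    """Next breeding population from the balance equation.

    ``kill_rates`` are the four cohort kill rates in :data:`COHORTS`
    order (adult male, adult female, young male, young female).
    """
    K = np.asarray(kill_rates, dtype=float)
    if K.shape != (4,):
        raise ValidationError("need one kill rate per cohort (4)")
    S = _survivals(model, K)
    R = reproduction_rate(model.reproduction, state.ponds, state.population)
    m = consts.male_proportion
    phi = consts.summer_survival_ratio
    gS = consts.bias_correction_survival
    gR = consts.bias_correction_reproduction
    s_am, s_af, s_jm, s_jf = S
    core = m * s_am + (1.0 - m) * (s_af + gR * R * (s_jf + s_jm * phi))
    return float(gS * state.population * core * np.exp(eps_n))


def pond_transition(consts: BiologicalConstants, ponds: float, eps_p: float = 0.0) -> float:
    """Next pond count from the AR(1), clamped at zero."""
    if ponds < 0:
        raise ValidationError("ponds must be non-negative")
    return float(max(0.0, consts.pond_intercept + consts.pond_slope * ponds + eps_p))


def harvest_given_rate(
    model: ModelSpec,
    consts: BiologicalConstants,
    regs: RegulationSet,
    population,
    reproduction,
    harvest_rate,
):
    """Total retrieved harvest (millions) at a given adult-male harvest rate.

    Mirrors the cohort structure of the balance equation: fall cohort
    sizes are ``N*m`` adult males, ``N*(1-m)`` adult females, and young
    scaled by the (bias-corrected) age ratio; each cohort's harvest rate
    is the adult-male rate times its historic ratio, *not* adjusted for
    crippling loss (unretrieved kill is not harvest).
    """
    N = np.asarray(population, dtype=float)
    R = np.asarray(reproduction, dtype=float)
    h = np.asarray(harvest_rate, dtype=float)
    ratios = regs.cohort_ratios()
    m = consts.male_proportion
    phi = consts.summer_survival_ratio
    gR = consts.bias_correction_reproduction
    h_am, h_af, h_jm, h_jf = (ratios[i] * h for i in range(4))
    out = N * (m * h_am + (1.0 - m) * (h_af + gR * R * (h_jf + h_jm * phi)))
    return out if out.ndim else float(out)


def expected_total_harvest(
    model: ModelSpec,
    consts: BiologicalConstants,
    regs: RegulationSet,
    state: SystemState,
    harvest_noise: DiscreteNoise,
) -> float:
    """Expected retrieved harvest over a discretized harvest-rate draw."""
    R = reproduction_rate(model.reproduction, state.ponds, state.population)
    H = harvest_given_rate(model, consts, regs, state.population, R, harvest_noise.nodes)
    return float(harvest_noise.weights @ np.atleast_1d(H))


def _row_kron(A, B):
    """Row-wise Kronecker (Khatri-Rao) product of two CSR matrices.

    Row ``i`` of the result is ``kron(A[i], B[i])``; used to combine the
    independent population and pond sub-kernels into a joint kernel
    without densifying.
    """
    A = sp.csr_matrix(A)
    B = sp.csr_matrix(B)
    n_rows = A.shape[0]
    ca = np.diff(A.indptr)
    cb = np.diff(B.indptr)
    row_of_a = np.repeat(np.arange(n_rows), ca)
    cb_per_entry = cb[row_of_a]
    total = int(cb_per_entry.sum())
    # segmented arange over each A-entry's B-row block
    starts = np.concatenate([[0], np.cumsum(cb_per_entry)[:-1]])
    inner = (
        np.arange(total)
        - np.repeat(starts, cb_per_entry)
        + np.repeat(B.indptr[row_of_a], cb_per_entry)
    )
    data = np.repeat(A.data, cb_per_entry) * B.data[inner]
    cols = np.repeat(A.indices, cb_per_entry) * B.shape[1] + B.indices[inner]
    indptr = np.concatenate([[0], np.cumsum(ca * cb)])
    return sp.csr_matrix(
        (data, cols, indptr), shape=(n_rows, A.shape[1] * B.shape[1])
    )


@dataclass
class MallardTables:
    """Everything derived from one population model on one grid.

    ``kernel`` holds per-regulation transition matrices over the joint
    (N, P) grid with state index ``s = i_N * n_P + i_P``.  The per-node
    arrays keep the quadrature enumeration so that downstream consumers
    (the devalued-harvest objective, the simulator) can re-weight exactly
    the same outcomes instead of re-deriving them.
    """

    model: ModelSpec
    n_grid: Grid1D
    p_grid: Grid1D
    kernel: list  # per action, (S, S) dense or CSR
    expected_harvest: np.ndarray  # (S, A)
    expected_next_population: np.ndarray  # (S, A)
    reproduction: np.ndarray  # (S,)
    next_population_nodes: np.ndarray  # (A, S, n_h, n_eN)
    harvest_nodes: np.ndarray  # (A, S, n_h)
    harvest_noises: list = field(repr=False, default_factory=list)  # per action
    eps_n_noise: DiscreteNoise | None = field(repr=False, default=None)
    eps_p_noise: DiscreteNoise | None = field(repr=False, default=None)
    pond_kernel: np.ndarray | None = field(repr=False, default=None)  # (n_P, n_P)
    pond_next_nodes: np.ndarray | None = field(repr=False, default=None)  # (n_P, n_eP)

    @property
    def n_states(self) -> int:
        return self.n_grid.n * self.p_grid.n

    @property
    def n_actions(self) -> int:
        return len(self.kernel)

    def state_index(self, population: float, ponds: float) -> int:
        return self.n_grid.index_of(population) * self.p_grid.n + self.p_grid.index_of(ponds)

    def state_values(self):
        """(N, P) values per joint state index, as two (S,) arrays."""
        n_vals = np.repeat(self.n_grid.values, self.p_grid.n)
        p_vals = np.tile(self.p_grid.values, self.n_grid.n)
        return n_vals, p_vals


def build_model_kernel(
    model: ModelSpec,
    consts: BiologicalConstants,
    regs: RegulationSet,
    n_grid: Grid1D,
    p_grid: Grid1D,
    n_nodes: int = 5,
    sparse: bool | None = None,
) -> MallardTables:
    """Discretized transition kernel and expectation tables for one model.

    The three independent noise sources (harvest-rate draw, ``eps_N``,
    ``eps_P``) are each discretized with ``n_nodes`` Gauss-Hermite nodes;
    all combinations are enumerated, next states computed from the
    dynamics, and outcomes projected onto the grid by the two-point
    linear split.  The joint kernel factorizes as (population kernel) x
    (pond kernel) because ponds evolve independently of the population,
    the action, and the model.

    ``sparse`` selects the kernel storage; by default dense below 4096
    joint states, CSR above (the full published grid is 144 x 64 = 9216
    states, where dense per-action matrices would be unwieldy).
    """
    nN, nP = n_grid.n, p_grid.n
    S = nN * nP
    A = regs.n_regulations
    if sparse is None:
        sparse = S > 4096

    eps_n = gauss_hermite(0.0, consts.process_error_variance_N, n_nodes)
    eps_p = gauss_hermite(0.0, consts.process_error_variance_P, n_nodes)
    harvest_noises = [regs.harvest_noise(a, n_nodes) for a in range(A)]
    nh, ne = n_nodes, n_nodes

    n_vals = np.repeat(n_grid.values, nP)  # (S,)
    p_vals = np.tile(p_grid.values, nN)  # (S,)
    R = reproduction_rate(model.reproduction, p_vals, n_vals)  # (S,)

    m = consts.male_proportion
    phi = consts.summer_survival_ratio
    gS = consts.bias_correction_survival
    gR = consts.bias_correction_reproduction

    # cohort survivals per (action, h-node): (4 cohorts, A, nh)
    h_nodes = np.stack([hn.nodes for hn in harvest_noises])  # (A, nh)
    K = _cohort_kill_rates(regs, consts, h_nodes)  # (4, A, nh)
    s_am, s_af, s_jm, s_jf = _survivals(model, K)  # each (A, nh)

    # deterministic part of N' per (action, state, h-node)
    core = (
        m * s_am[:, None, :]
        + (1.0 - m)
        * (s_af[:, None, :] + gR * R[None, :, None] * (s_jf[:, None, :] + s_jm[:, None, :] * phi))
    )  # (A, S, nh)
    det = gS * n_vals[None, :, None] * core  # (A, S, nh)
    next_pop = det[..., None] * np.exp(eps_n.nodes)[None, None, None, :]  # (A, S, nh, ne)
    if not np.isfinite(next_pop).all():
        raise ValidationError("population transition produced non-finite values")

    # retrieved harvest per (action, state, h-node)
    harvest = harvest_given_rate(
        model, consts, regs, n_vals[None, :, None], R[None, :, None], h_nodes[:, None, :]
    )  # (A, S, nh)

    # pond sub-kernel (shared across actions and models)
    pond_next = np.maximum(
        0.0, consts.pond_intercept + consts.pond_slope * p_grid.values[:, None] + eps_p.nodes[None, :]
    )  # (nP, neP)
    lo_p, w_p = projection_split(pond_next, p_grid)
    TP = np.zeros((nP, nP))
    rows_p = np.repeat(np.arange(nP), ne)
    np.add.at(TP, (rows_p, lo_p.ravel()), (w_p * eps_p.weights[None, :]).ravel())
    np.add.at(
        TP,
        (rows_p, np.minimum(lo_p.ravel() + 1, nP - 1)),
        ((1.0 - w_p) * eps_p.weights[None, :]).ravel(),
    )

    # population sub-kernel per action: (S, nN)
    w_joint = (np.stack([hn.weights for hn in harvest_noises])[:, :, None]
               * eps_n.weights[None, None, :])  # (A, nh, ne)
    kernels = []
    TP_rows = TP[np.tile(np.arange(nP), nN)]  # (S, nP): pond row per joint state
    TP_rows_sp = sp.csr_matrix(TP_rows) if sparse else None
    for a in range(A):
        TN = np.zeros((S, nN))
        vals = next_pop[a].reshape(S, nh * ne)
        lo, w_lo = projection_split(vals, n_grid)
        wts = np.broadcast_to(w_joint[a].reshape(1, nh * ne), (S, nh * ne))
        rows = np.repeat(np.arange(S), nh * ne)
        np.add.at(TN, (rows, lo.ravel()), (w_lo * wts).ravel())
        np.add.at(
            TN,
            (rows, np.minimum(lo.ravel() + 1, nN - 1)),
            ((1.0 - w_lo) * wts).ravel(),
        )
        if sparse:
            kernels.append(_row_kron(sp.csr_matrix(TN), TP_rows_sp))
        else:
            T = (TN[:, :, None] * TP_rows[:, None, :]).reshape(S, S)
            kernels.append(T)

    expected_next_population = np.einsum("ashe,ahe->sa", next_pop, w_joint)
    wh = np.stack([hn.weights for hn in harvest_noises])  # (A, nh)
    expected_harvest = np.einsum("ash,ah->sa", harvest, wh)

    return MallardTables(
        model=model,
        n_grid=n_grid,
        p_grid=p_grid,
        kernel=kernels,
        expected_harvest=expected_harvest,
        expected_next_population=expected_next_population,
        reproduction=R,
        next_population_nodes=next_pop,
        harvest_nodes=harvest,
        harvest_noises=harvest_noises,
        eps_n_noise=eps_n,
        eps_p_noise=eps_p,
        pond_kernel=TP,
        pond_next_nodes=pond_next,
    )
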