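# Methods

## Decision problems

Both decision problems are stationary, infinite-horizon MDPs over a
finite joint grid of breeding population `N` and pond count `P`, with
four regulatory actions ordered closed < restrictive < moderate <
liberal.  Optimization uses the average-reward (ergodic) criterion,
i.e. a discount factor of 1, consistent with a long-term sustainability
objective; a discounted solver is retained for testing against closed
forms.

**Post-survey.** The state is `x = (N, P)`, observed before the
decision.  For a fixed weight vector `q` over the K alternative models,
the kernel and utility are the convex combinations `Σ q_k P_k` and
`Σ q_k U_k` (passive adaptive form: `q` is a parameter of the solve, not
a dynamic state, and is updated by Bayes' rule outside the optimization).

**Pre-survey.** The state is augmented to `(a_prev, x_lag)`, ordered
previous-action-major.  Choosing action `a` pays the lag-projected
utility `Σ_k q_k (P_k[a_prev] U_k)[x_lag, a]` and moves to `(a, x_t)`
with `x_t` drawn from the weight-averaged lagged kernel under `a_prev`.

### Reward averaging in the pre-survey problem

The lag-projected utility above ("per-model" averaging, the default)
couples each model's lag kernel with its own utility.  Algebraically it
equals the conditional expectation of the utility given the realized
current state, with the model weighted by its posterior given that state
— it embeds one step of Bayesian conditioning.  The passive post-survey
problem, by contrast, scores utility with the *prior* weights even after
the state is observed.  A consequence worth knowing: at mixed beliefs the
pre-survey optimal gain can *exceed* the passive post-survey gain by
order 1% — not because less information helps, but because the two
passive formulations weight the per-model utilities differently.
`assemble_pre(..., reward_averaging="mixture")` instead averages kernel
and utility separately (`(Σ q_k P_k)(Σ q_k U_k)`), which makes the
pre-survey problem an exact information coarsening of the post-survey
mixture MDP; in that formulation the information bound
`gain_pre ≤ gain_post` is a theorem, and the test suite asserts it there.
The two formulations coincide at vertex beliefs (single models).

### Average-reward solver

Relative value iteration with an aperiodicity (damping) transform:
`v ← (1 − τ) v + τ (T v)`, τ = 0.5 by default, normalized at a reference
state each sweep.  The transform leaves the gain and the optimal policy
unchanged while guaranteeing convergence on unichain problems with
periodic structure (e.g. deterministic cycles).  Convergence is declared
on the span seminorm of the differential `T v − v` (default tolerance
1e-8); the gain is the midpoint of that differential.  The source
analysis does not state its convergence criterion; these are this
package's choices.  Ties in every greedy argmax break to the lowest
action index — the most conservative regulation.

If the differential becomes stationary while its span stays above
tolerance, the gain depends on the starting state (multichain problem);
the solver warns and returns per-state gains instead of a scalar.  This
path is exercised deliberately by the identity-lag-kernel reduction,
where every state is absorbing.

Action constraints are handled by masking (a `−inf` surrogate in the
maximization), keeping kernels rectangular.

## Population models

Breeding population (millions) follows the balance equation

    N' = γ_S N { m S_AM + (1−m) [ S_AF + γ_R R (S_JF + S_JM φ) ] } exp(ε_N)

with ε_N ~ N(0, 0.0184).  Survival under the additive hypothesis is
`s0 (1 − K)`; under the compensatory hypothesis it is `s0` up to the
threshold `K = 1 − s0` and `1 − K` beyond.  Baseline survivals: additive
0.7896 (male) / 0.6886 (female); compensatory 0.6467 / 0.5965.  The fall
age ratio is `R = max(0, a0 + a1 P + a2 N)` with (1.1390, 0.1376,
−0.1131) for strong and (0.7166, 0.1083, −0.0373) for weak density
dependence.  Ponds follow `P' = max(0, 2.2127 + 0.3420 P + ε_P)`,
ε_P ~ N(0, 1.257), independent of model and action.

Partial controllability: each regulation induces a normal adult-male
harvest-rate distribution — means (0.0088, 0.0552, 0.0977, 0.1139), SDs
(0.0020, 0.0129, 0.0215, 0.0179) — discretized by 5 Gauss–Hermite nodes
(clamped at zero; only the closed-season distribution could dip below
it).  Other cohorts scale by fixed ratios 1.5407 (young male), 0.7191
(adult female), 1.1175 (young female).  The total kill rate inflates the
retrieved rate by a 20% crippling loss, `K = ratio·h / (1 − 0.2)`, capped
at 1; a multiplicative convention `ratio·h·(1 + 0.2)` is available by
config since "adjusted for crippling loss" admits either reading.

Total retrieved harvest mirrors the cohort structure of the balance
equation with fall cohort sizes `N m`, `N (1−m)` and young scaled by
`γ_R R`:

    H = N [ m h_AM + (1−m) (h_AF + γ_R R (h_JF + h_JM φ)) ]

using *unadjusted* cohort harvest rates (unretrieved kill is not
harvest).  The composition of total harvest from cohorts is not spelled
out in the source analysis; this form is internally consistent with the
population model and is isolated in `harvest_given_rate` for replacement.

**Constants without printed values.**  The male proportion `m`, summer
survival ratio `φ = φ_F/φ_M`, and bias corrections `γ_S, γ_R` live in the
management protocol's supplementary material, not the main text.  The
package defaults — m = 0.55, φ = 0.9, γ_S = γ_R = 1.0 — are documented
placeholders chosen once as field-plausible values (the male proportion
of the mid-continent breeding population is a little over half; female
summer survival is somewhat below male because of nesting mortality).
Every one is configurable.

## Discretization

State grids are uniform and inclusive.  The published description of the
grids is internally inconsistent ("increments of 0.125 over the interval
0.5 to 18 ... a total of 144 and 64 discrete values": 0.5–18 gives 141
points, not 144).  The defaults honor the printed *counts*: 144 × 64
states from lower bounds of 0.125.  Bounds and steps are configurable,
and all tests and the acceptance run use coarser grids (steps 0.5–2.0)
chosen for problem sizes that solve in seconds; the policy gain on the
full 9216-state grid agrees with the step-0.5 grid to about 0.1%.

Each normal process error is replaced by the probabilists' Gauss–Hermite
rule rescaled to its mean and variance (exact first and second moments
for ≥ 2 nodes; 5 nodes by default, matching the published setup).  The
three noise sources (harvest-rate draw, ε_N, ε_P) are independent, and
their product enumeration defines both the kernels and every expectation
table, so utilities, expected harvest and expected next population are
all consistent re-weightings of the same outcomes.

Off-node outcomes are projected onto the grid by a two-point linear
split between the bracketing nodes — mean-preserving for interior
values — with out-of-range outcomes clamped to the boundary node (the
source truncates the state space without stating boundary behavior).
The joint kernel factorizes as the row-wise Kronecker product of the
population and pond sub-kernels; above 4096 joint states kernels are
stored sparse (CSR).

The devaluation factor α is evaluated at the *continuous* next-population
node, before grid projection, jointly with the harvest at the same
harvest-rate node: the objective takes `E[α(N') H]`, not
`α(E[N']) E[H]`.

## Objective and constraints

`α(N') = 1` at or above the 8.5-million goal, `N'/8.5` below; utility is
`E[α(N') H]` per model, weight-averaged where required.  Closed seasons
are infeasible when the population at decision time is ≥ 4.75 million —
observed `N` post-survey, projected `E[N | x_lag, q, a_prev]` pre-survey
(the projection uses the same quadrature enumeration as the kernels, on
the continuous next-population values).  The boundary is inclusive
(exactly 4.75 excludes the closed season); the printed inequality is
ambiguous about the boundary and this convention is fixed here.

## Beliefs and updating

Weights over the four models (order SaRs, SaRw, ScRs, ScRw) live on the
286-point simplex lattice at step 0.1.  Policies are solved per lattice
point, lazily and cached (the family supports eager solving too).
Likelihood for the Bayesian update is the discretized-kernel probability
of the observed grid transition, `P_k(x' | x, a)`, for both the
population and pond dimensions; ponds contribute identically across
models and cancel in the normalization, but are included for generality.
An off-grid observation is projected first and the likelihood is the
projection-weighted mixture.  A continuous-density likelihood is a
reasonable alternative for field data; the discrete-kernel choice matches
a simulator that evolves the discretized system.  Nearest-belief lookup
is Euclidean with ties to the lowest lattice index.

## Simulation

Monte Carlo evaluation simulates the discretized dynamics of one
designated true model.  Each replicate-year draws, in fixed order, a
harvest-rate node, an ε_N node, an ε_P node, and two projection-split
uniforms; the next state is *sampled* from the projection split (so the
simulated chain is exactly the discretized kernel), and realized harvest
uses the sampled harvest-rate node — the same draw that drives mortality
— so harvest variability reflects partial controllability.  Whether the
original simulations sampled or expected the harvest rate is not stated;
sampling is this package's documented choice.

Beliefs update continuously every year and are never snapped to the
lattice; only the policy lookup is discretized, which prevents premature
absorption at certainty.  Post-survey sequencing: observe, update, act.
Pre-survey: act on `(x_lag, a_prev)` and the belief updated through
`x_lag`, then observe.  The pre-survey run initializes the lagged state
and action (population 6, ponds 4, liberal) and realizes the first
current state from them, mirroring the published initialization.

One child seed per replicate is spawned from the master seed, giving
bit-identical reruns and common random numbers across modes and true
models at the same master seed.

Study conditions default to the published ones: 10,000 replicates of 50
years, initial population 6 million, ponds 4 million, initial belief
(0.1, 0.5, 0.1, 0.3).  The acceptance run uses 500 replicates on the
step-0.5 grid — at 500 replicates the Monte Carlo standard error of a
mean weight is below 0.02, ample for a threshold-crossing year — and
reaches mean weight 0.9 on the true model in year 12–14 depending on
seed.

## What the synthetic dynamics do and do not show

The simulator generates data from one of the four candidate models, so
the Bayesian updater is always well-specified: one weight converging to
1 demonstrates that the machinery identifies a *correct* model quickly,
not that real mallard dynamics are any of the four (in operation, no
model has emerged dominant over decades, suggesting none is close).
Sampling error in the surveys, sex/age structure, spatial structure and
harvest-regulation changes over time are all outside the model set, so
the simulated learning speed is an upper bound on what field data would
deliver.

## Known limitations

- Active adaptive optimization (beliefs as a dynamic optimization state)
  and POMDP treatments of survey error are out of scope.
- The average-reward solver assumes unichain structure; multichain
  problems are detected and reported with per-state gains, not solved
  for optimal multichain policies.
- The pre-survey augmented MDP is assembled dense; at full grid
  resolution (36,864 augmented states) it is memory-hungry, and the
  pre-survey analyses here use coarsened grids.
- Operational values of m, φ, γ_S, γ_R are placeholders (see above);
  policies are qualitatively robust to them but gains shift.
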