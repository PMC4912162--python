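# harvestmdp

Markov decision processes for resource harvesting when the regulatory
decision must be made **before** the current state of the system has been
surveyed, with structural uncertainty handled by passive adaptive
management.

The package is aimed at quantitative ecologists and natural-resource
decision analysts.  It provides a generic discrete MDP layer (discounted
and average-reward solvers), tools to discretize continuous stochastic
population dynamics into transition kernels (uniform state grids,
Gauss–Hermite quadrature for normal process errors, mean-preserving grid
projection), Bayesian updating of weights over alternative system models,
and a Monte Carlo simulator for evaluating adaptive policies.  It ships a
fully parameterized case study: the adaptive harvest management (AHM) of
mid-continent mallards in the United States.

## The decision problem

A standard (post-survey) harvest MDP chooses an action after observing the
system state `x_t` (here: breeding population `N`, in millions, and May
pond count `P`, in millions).  Under structural uncertainty, `K`
alternative models with kernels `P_k(x' | x, a)` are carried with weights
`q` (the *model state*), and the passive adaptive policy solves, for each
fixed `q`,

    V(x) = max_a [ Σ_k q_k U_k(x, a) + Σ_{x'} Σ_k q_k P_k(x' | x, a) V(x') ]

under the average-reward criterion (discount factor 1), with `q` updated
by Bayes' rule outside the optimization as each year's survey arrives.

When the decision precedes the survey (*pre-survey*), neither `x_t` nor
the updated `q_t` is available; the decision state is augmented to the
lagged state and previous action, `(x_{t-1}, a_{t-1})`, with reward

    U(x_{t-1}, q, a_{t-1}, a) = Σ_{x_t} Σ_k q_k P_k(x_t | x_{t-1}, a_{t-1}) U_k(x_t, a)

and transitions to `(x_t, a)` under the weight-averaged lagged kernel.

The mallard case study crosses two survival hypotheses (harvest mortality
**a**dditive vs **c**ompensatory) with two reproduction hypotheses
(**s**trong vs **w**eak density dependence), giving models SaRs, SaRw,
ScRs, ScRw.  The objective maximizes long-run mean harvest devalued by
`α(N') = min(1, N'/8.5)` whenever next year's expected population falls
below 8.5 million, and a closed season is unavailable whenever the
population at decision time (observed or projected) is at least
4.75 million.

## Worked example

Solve the post-survey passive adaptive policy for the 2015 model weights
on a coarsened grid, then evaluate it by simulation with the additive/weak
model generating the data:

```python
from harvestmdp.case import build_case
from harvestmdp.config import GridConfig, RunConfig, SolverConfig
from harvestmdp.simulate import SimulationConfig, run_simulation

cfg = RunConfig(
    population_grid=GridConfig(0.5, 18.0, 0.5),
    pond_grid=GridConfig(0.5, 8.0, 0.5),
    solver=SolverConfig(tol=1e-6),
)
case = build_case(cfg)
family = case.family("post")          # policies solved lazily per belief

policy = family.lookup((0.0104, 0.6861, 0.0011, 0.3024))  # 2015 weights
print(f"long-run mean devalued harvest: {policy.gain:.3f} million birds/yr")
print(policy.to_frame()[policy.to_frame().ponds == 4.0].iloc[8:14])

sim = SimulationConfig(true_model="SaRw", replicates=500, horizon=50,
                       seed=1, mode="post")
summary = run_simulation(sim, family, case.tables)
print("mean weight on SaRw reaches 0.9 in year",
      summary.first_year_weight_reaches("SaRw", 0.9))
```

Output:

```
long-run mean devalued harvest: 1.852 million birds/yr
 population  ponds  regulation
        4.5    4.0      closed
        5.0    4.0 restrictive
        5.5    4.0 restrictive
        6.0    4.0 restrictive
        6.5    4.0    moderate
        7.0    4.0     liberal
mean weight on SaRw reaches 0.9 in year 13
```

The gain is the stationary mean of `α(N')·H` in millions of birds per
year.  The policy column shows the familiar AHM structure at 4 million
ponds: seasons close at very low populations and liberalize as the
population grows (closed seasons are constrained away at and above
4.75 million).  In simulation, annual Bayesian updating identifies the
data-generating model (mean weight ≥ 0.9) within about a decade and a
half from the initial weights (0.1, 0.5, 0.1, 0.3).

A command-line interface wraps the same steps:

```
harvestmdp solve-post --belief 0.0104 0.6861 0.0011 0.3024 --out policies/
harvestmdp solve-pre  --belief 0 1 0 0 --out policies/
harvestmdp simulate --true-model SaRw --mode post --replicates 1000 --seed 1
```

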