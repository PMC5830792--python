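# mixsis

Tools for studying how **mixing between two heterogeneous groups shapes a
contagion process** — the spread of a disease, a behaviour, a belief — when
the groups differ in their propensity to catch it. The central policy
question is whether segregating or mixing a *sensitive* and a *resistant*
group raises or lowers long-run diffusion in each group, and whether some
mixing levels are *Pareto-inefficient* (both groups could do better at a
different level).

## Model

Two equally sized groups play a susceptible–infected–susceptible (SIS)
process. Each period an individual interacts with probability *p*; with
probability *m* ∈ [0, 1] (the **mixing level**) the partner comes from the
other group. A susceptible member of group *i* meeting an infected partner
becomes infected with probability *υᵢ*; infected members recover with
probability *δᵢ*. In the large-population limit the infected fractions
*ρᵢ* follow

ρ̇ᵢ = δᵢ [ λᵢ (1 − ρᵢ)(m ρⱼ + (1 − m) ρᵢ) − ρᵢ ],  λᵢ = p υᵢ / δᵢ,

so everything is governed by the **effective adoption rates** (λ₁, λ₂)
(canonically λ₁ ≤ λ₂: group 2 is the sensitive group) and *m*. The package
provides:

- **Thresholds** — the no-diffusion state (0, 0) loses stability below the
  mixing threshold m̄ = 1 − (1 − λ₁λ₂)/(λ₁ + λ₂ − 2λ₁λ₂) when
  λ₂ > 1 ≥ λ₁λ₂; closed form and an independent eigenvalue bisection.
- **Endemic equilibria** — the almost-globally-stable positive state at any
  *m*, with closed forms at the extremes: ρᵢᴱ = max(0, 1 − 1/λᵢ) at *m* = 0
  and ((λ₁λ₂−1)/(λ₁λ₂+λ₂), (λ₁λ₂−1)/(λ₁λ₂+λ₁)) at *m* = 1.
- **Regimes A–E** of the (λ₁, λ₂) plane: where the resistant group's
  equilibrium level is non-monotonic in *m*, where the population average
  peaks at interior mixing, and where pure trade-offs rule.
- **Pareto analysis** — mixing levels dominated by another level for both
  groups at once, and optimal *m* for simple planner objectives
  (minimise/maximise the average, minimise the between-group gap).
- **A general state-conditional model** in which both adoption *and*
  recovery rates depend on the partner's state (υ|S, υ|I, δ|I, δ|S per
  group), with reaction functions, curvature classification, and the same
  regime analyses.
- **A finite-population agent simulator** whose per-period expected update
  is exactly one Euler step of the mean dynamics, for checking how fast the
  stochastic process approaches the ODE as group sizes grow.

## Worked example

The case λ = (0.55, 2) is the showcase for inefficient mixing. Classify it
and look at its equilibrium curve:

```bash
$ mixsis classify --lambda1 0.55 --lambda2 2
{
  "label": "C",
  "boundary_flags": [],
  "canonical_swapped": false
}

$ mixsis curve --lambda1 2 --lambda2 5 --grid 5
m,rho1,rho2,avg,diff,positive
0,0.5,0.8,0.65,0.3,True
0.25,0.548439811954,0.783768984561,0.666104398257,0.235329172608,True
0.5,0.573384418152,0.770646232739,0.672015325446,0.197261814588,True
0.75,0.589132370409,0.759538476504,0.674335423456,0.170406106095,True
1,0.6,0.75,0.675,0.15,True
```

The λ = (2, 5) curve (regime E) shows the pure trade-off: the resistant
group's level `rho1` rises with mixing while the sensitive group's `rho2`
falls, meeting the bipartite closed forms (0.6, 0.75) at *m* = 1. In
regime C the resistant curve instead peaks at interior *m*, which creates
dominated mixing levels:

```bash
$ mixsis pareto --lambda1 0.3 --lambda2 4
m_lo,m_hi,witness_m
0.145,0.995,1
```

— every mixing level in [0.145, 0.995] leaves *both* groups worse off than
full mixing (*m* = 1). In Python:

```python
>>> from mixsis import EffectiveRates, solve_equilibrium
>>> res = solve_equilibrium(EffectiveRates(0.55, 2.0), m=0.6)
>>> (round(res.state.rho1, 4), round(res.state.rho2, 4))
(0.0782, 0.205)
```

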