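"""Stochastic agent-based counterpart of the mean-field dynamics.

Two groups of binary-state agents are updated synchronously each period:
every agent independently interacts with probability p, draws a partner
from the other group with probability m (its own group otherwise,
uniformly and excluding itself), and then, depending on the partner's
start-of-period state, may switch state. For the SIS variant a
susceptible agent with an infected partner becomes infected with
probability upsilon_i (times an optional per-agent susceptibility
multiplier, capped at 1) and every infected agent recovers with
probability delta_i. For the state-conditional variant every agent
interacts each period and the four conditional rates act as transition
probabilities.

The per-period expected change of the infected fractions is exactly one
Euler step of the mean dynamics, so ensemble averages converge to the ODE
solution as the group sizes grow. Within-group heterogeneity is emulated
by lognormal susceptibility multipliers with mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sis_core import (
    EffectiveRates,
    SISParameters,
    ValidationError,
    check_mixing_level,
    effective_rates,
)
from .general_contagion import ConditionalRates, GeneralModel
from . import equilibria, general_contagion


class ConfigurationError(ValueError):
    """The simulation configuration is inconsistent."""


@dataclass
class AgentPopulation:
    """Binary infection states (and optional susceptibility multipliers)
    for the two groups."""

    state1: np.ndarray  # bool, shape (n1,)
    state2: np.ndarray  # bool, shape (n2,)
    mult1: np.ndarray | None = None  # positive, mean ~1
    mult2: np.ndarray | None = None

    def __post_init__(self) -> None:
        for s in (self.state1, self.state2):
            if s.dtype != bool or s.ndim != 1:
                raise ValidationError("agent states must be 1-D bool arrays")
        for mu in (self.mult1, self.mult2):
            if mu is not None and (np.any(mu <= 0) or not np.all(np.isfinite(mu))):
                raise ValidationError("multipliers must be positive and finite")

    @property
    def sizes(self) -> tuple[int, int]:
        return (len(self.state1), len(self.state2))

    @property
    def fractions(self) -> tuple[float, float]:
        return (float(self.state1.mean()), float(self.state2.mean()))


@dataclass
class SimConfig:
    """Settings for an ensemble of finite-population runs.

    ``params`` is either raw SIS parameters or a state-conditional
    :class:`GeneralModel` (whose own ``m`` is ignored in favour of the
    config's). ``heterogeneity_sigma`` > 0 draws lognormal susceptibility
    multipliers with mean 1 and log-scale sigma, once per replicate.
    """

    params: SISParameters | GeneralModel
    m: float
    n1: int = 10_000
    n2: int = 10_000
    periods: int = 2_000
    replicates: int = 20
    seed: int = 0
    initial_fraction: float = 0.5
    heterogeneity_sigma: float = 0.0

    def __post_init__(self) -> None:
        check_mixing_level(self.m)
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigurationError("group sizes must be at least 1")
        if self.m < 1.0 and min(self.n1, self.n2) < 2:
            raise ConfigurationError(
                "within-group partnering (m < 1) needs at least 2 agents "
                "per group")
        if self.periods < 1 or self.replicates < 1:
            raise ConfigurationError("periods and replicates must be >= 1")
        if not 0.0 <= self.initial_fraction <= 1.0:
            raise ConfigurationError("initial_fraction must lie in [0, 1]")
        if self.heterogeneity_sigma < 0.0:
            raise ConfigurationError("heterogeneity_sigma must be >= 0")

    @property
    def is_general(self) -> bool:
        return isinstance(self.params, GeneralModel)


def _own_group_partners(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform partner indices within a group, excluding self."""
    idx = rng.integers(0, n - 1, size=n)
    idx += idx >= np.arange(n)
    return idx


def _partner_infected(state_own: np.ndarray, state_other: np.ndarray,
                      m: float, rng: np.random.Generator) -> np.ndarray:
    n = len(state_own)
    cross = rng.random(n) < m
    own_idx = _own_group_partners(n, rng) if n > 1 else np.zeros(n, dtype=int)
    other_idx = rng.integers(0, len(state_other), size=n)
    return np.where(cross, state_other[other_idx], state_own[own_idx])


def step(pop: AgentPopulation, config: SimConfig,
         rng: np.random.Generator) -> AgentPopulation:
    """One synchronous period: all transitions read start-of-period states."""
    m = config.m
    new_states = []
    groups = ((pop.state1, pop.state2, pop.mult1),
              (pop.state2, pop.state1, pop.mult2))
    for gi, (own, other, mult) in enumerate(groups, start=1):
        n = len(own)
        partner_inf = _partner_infected(own, other, m, rng)
        if config.is_general:
            g = config.params.group(gi)
            nu = np.where(partner_inf, g.nu_I, g.nu_S)
            if mult is not None:
                nu = np.minimum(nu * mult, 1.0)
            delta = np.where(partner_inf, g.delta_I, g.delta_S)
            infect = ~own & (rng.random(n) < nu)
            recover = own & (rng.random(n) < delta)
        else:
            p = config.params.p
            upsilon = (config.params.upsilon1, config.params.upsilon2)[gi - 1]
            delta = (config.params.delta1, config.params.delta2)[gi - 1]
            interact = rng.random(n) < p
            u = np.full(n, upsilon)
            if mult is not None:
                u = np.minimum(u * mult, 1.0)
            infect = (~own & interact & partner_inf & (rng.random(n) < u))
            recover = own & (rng.random(n) < delta)
        new_states.append((own | infect) & ~recover)
    return AgentPopulation(new_states[0], new_states[1], pop.mult1, pop.mult2)


def deterministic_step(rho, params: SISParameters, m: float) -> np.ndarray:
    """Expected-value (zero-noise) update of the infected fractions; equals
    one Euler step of the mean dynamics with unit time step."""
    m = check_mixing_level(m)
    r = np.asarray(rho, dtype=float)
    ups = np.array([params.upsilon1, params.upsilon2])
    del_ = np.array([params.delta1, params.delta2])
    partner = np.array([m * r[1] + (1 - m) * r[0], m * r[0] + (1 - m) * r[1]])
    return r + params.p * ups * (1 - r) * partner - del_ * r


def _init_population(config: SimConfig, seed_seq: np.random.SeedSequence
                     ) -> tuple[AgentPopulation, np.random.Generator]:
    init_ss, mult_ss, run_ss = seed_seq.spawn(3)
    rng_init = np.random.default_rng(init_ss)
    states = []
    for n in (config.n1, config.n2):
        k = int(round(config.initial_fraction * n))
        s = np.zeros(n, dtype=bool)
        s[rng_init.permutation(n)[:k]] = True
        states.append(s)
    mults: list[np.ndarray | None] = [None, None]
    sigma = config.heterogeneity_sigma
    if sigma > 0.0:
        rng_mult = np.random.default_rng(mult_ss)
        mults = [np.exp(rng_mult.normal(-0.5 * sigma ** 2, sigma, size=n))
                 for n in (config.n1, config.n2)]
    pop = AgentPopulation(states[0], states[1], mults[0], mults[1])
    return pop, np.random.default_rng(run_ss)


@dataclass
class EnsembleSummary:
    """Per-period ensemble means and quasi-stationary final-window report.

    ``final_window_mean`` averages the last 20% of periods over replicates
    that did not go extinct; ``final_window_stderr`` is the standard error
    of the per-replicate window means.
    """

    t: np.ndarray
    mean_rho: np.ndarray          # (periods+1, 2) across all replicates
    stderr_rho: np.ndarray        # (periods+1, 2)
    replicate_final: np.ndarray   # (replicates, 2) final-window means
    extinct: np.ndarray           # (replicates,) bool
    final_window_mean: np.ndarray
    final_window_stderr: np.ndarray
    config: SimConfig

    def trajectories_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "rho1": self.mean_rho[:, 0], "rho2": self.mean_rho[:, 1],
            "stderr1": self.stderr_rho[:, 0], "stderr2": self.stderr_rho[:, 1],
        })


def run_single(config: SimConfig, seed_seq=None) -> np.ndarray:
    """One replicate; returns the (periods+1, 2) trajectory of fractions."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    pop, rng = _init_population(config, seed_seq)
    traj = np.empty((config.periods + 1, 2))
    traj[0] = pop.fractions
    for k in range(1, config.periods + 1):
        pop = step(pop, config, rng)
        traj[k] = pop.fractions
    return traj


def run_ensemble(config: SimConfig) -> EnsembleSummary:
    """Run all replicates (seeds spawned deterministically from
    ``config.seed``) and summarise."""
    root = np.random.SeedSequence(config.seed)
    trajs = np.stack([run_single(config, ss)
                      for ss in root.spawn(config.replicates)])
    window = max(1, int(0.2 * config.periods))
    rep_final = trajs[:, -window:, :].mean(axis=1)
    extinct = trajs[:, -1, :].sum(axis=1) == 0.0
    alive = ~extinct
    use = rep_final[alive] if alive.any() else rep_final
    nrep = config.replicates
    return EnsembleSummary(
        t=np.arange(config.periods + 1),
        mean_rho=trajs.mean(axis=0),
        stderr_rho=(trajs.std(axis=0, ddof=1) / np.sqrt(nrep)
                    if nrep > 1 else np.zeros_like(trajs[0])),
        replicate_final=rep_final,
        extinct=extinct,
        final_window_mean=use.mean(axis=0),
        final_window_stderr=(use.std(axis=0, ddof=1) / np.sqrt(len(use))
                             if len(use) > 1 else np.zeros(2)),
        config=config,
    )


def compare_to_meanfield(summary: EnsembleSummary) -> dict:
    """Deviation of the ensemble's quasi-stationary means from the
    mean-field equilibrium under the same parameters."""
    config = summary.config
    if config.is_general:
        model = GeneralModel(config.params.group1, config.params.group2,
                             config.m)
        res = general_contagion.general_equilibrium(model,
                                                    check_uniqueness=False)
        target = res.state.as_array()
    else:
        rates = effective_rates(config.params)
        res = equilibria.solve_equilibrium(rates, config.m)
        target = np.array(rates.user_order(*res.state.as_array()))
    dev = summary.final_window_mean - target
    return {
        "meanfield_equilibrium": target,
        "ensemble_mean": summary.final_window_mean,
        "deviation": dev,
        "max_abs_deviation": float(np.max(np.abs(dev))),
        "n_extinct": int(summary.extinct.sum()),
    }


def size_scan(config: SimConfig, sizes) -> list[dict]:
    """Re-run the ensemble at several population sizes and report the
    mean-field deviation for each (law-of-large-numbers check)."""
    out = []
    for n in sizes:
        cfg = SimConfig(params=config.params, m=config.m, n1=n, n2=n,
                        periods=config.periods, replicates=config.replicates,
                        seed=config.seed,
                        initial_fraction=config.initial_fraction,
                        heterogeneity_sigma=config.heterogeneity_sigma)
        rep = compare_to_meanfield(run_ensemble(cfg))
        rep["n_per_group"] = n
        out.append(rep)
    return out
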