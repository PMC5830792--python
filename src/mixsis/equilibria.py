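"""Endemic equilibria of the two-group SIS model and their dependence on m.

The positive (endemic) stationary state, when it exists, attracts every
non-null initial condition. It exists iff lambda2 > 1 and either
lambda1*lambda2 > 1 or m < mbar (the origin-stability threshold). This
module computes that state by scalar root-finding on the composed
*reaction functions* — each group's stationary infected fraction as a
function of the other group's — and tabulates it over a grid of mixing
levels together with the population average and the between-group gap.

Closed forms exist at the segregated (m=0) and bipartite (m=1) extremes:

    m=0 : rho_i = max(0, 1 - 1/lambda_i)            (isolated SIS)
    m=1 : rho_1 = (L - 1)/(L + lambda2),
          rho_2 = (L - 1)/(L + lambda1),  L = lambda1*lambda2 > 1

and serve as independent oracles for the numerical solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .sis_core import (
    EffectiveRates,
    PopulationState,
    ValidationError,
    check_mixing_level,
    mbar_formula,
    sis_jacobian,
    sis_rhs,
)

#: below this, an equilibrium component counts as extinct
POSITIVITY_THRESHOLD = 1e-9

#: eigenvalue real parts up to this still count as (marginally) stable
STABILITY_TOL = 1e-8


class SolverError(RuntimeError):
    """The equilibrium solver failed to reach its residual tolerance."""


def reaction_sis(rho_j: float, lambda_i: float, m: float) -> float:
    """Largest stationary infected fraction of one group given the other's.

    Returns the largest root in [0, 1] of the per-group stationarity
    condition  lambda_i*(1-rho)*(m*rho_j + (1-m)*rho) - rho = 0  with rho_j
    held fixed. The stationarity polynomial is a downward parabola that is
    non-negative at 0 and equals -1 at rho=1, so the largest root always
    lies in [0, 1).
    """
    m = check_mixing_level(m)
    if not 0.0 <= rho_j <= 1.0:
        raise ValidationError(f"rho_j must lie in [0, 1], got {rho_j!r}")
    if lambda_i <= 0.0:
        raise ValidationError(f"lambda_i must be positive, got {lambda_i!r}")
    if m == 1.0:
        # linear case: no within-group transmission
        s = lambda_i * rho_j
        return s / (1.0 + s)
    # -a*rho^2 + beta*rho + gamma with a > 0, gamma >= 0
    a = lambda_i * (1.0 - m)
    gamma = lambda_i * m * rho_j
    beta = a - gamma - 1.0
    disc = math.sqrt(beta * beta + 4.0 * a * gamma)
    if beta > 0.0:
        return (beta + disc) / (2.0 * a)
    # numerically stable branch when beta <= 0 (avoids cancellation)
    if gamma == 0.0:
        return 0.0
    return 2.0 * gamma / (disc - beta)


@dataclass(frozen=True)
class EquilibriumResult:
    """An equilibrium state with solver diagnostics."""

    state: PopulationState
    positive: bool
    residual: float
    stable: bool


def positive_state_exists(rates: EffectiveRates, m: float) -> bool:
    """Whether the endemic state exists at mixing level m: lambda2 > 1 and
    either lambda1*lambda2 > 1 or m below the mixing threshold."""
    m = check_mixing_level(m)
    if rates.lambda2 <= 1.0:
        return False
    if rates.product > 1.0:
        return True
    return m < mbar_formula(rates)


def solve_equilibrium(rates: EffectiveRates, m: float,
                      tol: float = 1e-12) -> EquilibriumResult:
    """Compute the almost-globally-stable equilibrium at mixing level m.

    When no positive state exists the no-diffusion state (0, 0) is
    returned. Otherwise the endemic state is the largest fixed point of the
    composed reaction map h(rho2) = R2(R1(rho2)); h - id is positive just
    above 0 and negative at 1, so Brent's method on [eps, 1] is guaranteed
    to bracket it.
    """
    m = check_mixing_level(m)
    l1, l2 = rates.lambda1, rates.lambda2
    if not positive_state_exists(rates, m):
        state = PopulationState(0.0, 0.0)
        eig = np.linalg.eigvals(sis_jacobian((0.0, 0.0), rates, m))
        return EquilibriumResult(state, positive=False, residual=0.0,
                                 stable=bool(np.max(eig.real) <= STABILITY_TOL))

    def gap(r2: float) -> float:
        return reaction_sis(reaction_sis(r2, l1, m), l2, m) - r2

    lo = 1e-14
    if gap(lo) <= 0.0:  # numerically indistinguishable from extinction
        state = PopulationState(0.0, 0.0)
        return EquilibriumResult(state, positive=False, residual=0.0,
                                 stable=True)
    r2 = brentq(gap, lo, 1.0, xtol=1e-15, rtol=8.9e-16)
    r1 = reaction_sis(r2, l1, m)
    residual = float(np.max(np.abs(sis_rhs((r1, r2), rates, m))))
    if residual > max(tol, 1e-11):
        raise SolverError(
            f"equilibrium residual {residual:.2e} exceeds tolerance at "
            f"m={m}, rates=({l1}, {l2})")
    eig = np.linalg.eigvals(sis_jacobian((r1, r2), rates, m))
    positive = r1 > POSITIVITY_THRESHOLD and r2 > POSITIVITY_THRESHOLD
    # with lambda1*lambda2 <= 1 the resistant group dies out exactly at the
    # extremes m=0 (no seed) — classify by components, not by existence
    return EquilibriumResult(PopulationState(r1, r2), positive=positive,
                             residual=residual,
                             stable=bool(np.max(eig.real) <= STABILITY_TOL))


def closed_form_endpoints(rates: EffectiveRates):
    """Equilibria at the segregated (m=0) and bipartite (m=1) extremes.

    Returns ``(rho_m0, rho_m1)``, each a (rho1, rho2) pair in canonical
    group order.
    """
    l1, l2 = rates.lambda1, rates.lambda2
    m0 = (max(0.0, 1.0 - 1.0 / l1), max(0.0, 1.0 - 1.0 / l2))
    prod = rates.product
    if prod > 1.0:
        m1 = ((prod - 1.0) / (prod + l2), (prod - 1.0) / (prod + l1))
    else:
        m1 = (0.0, 0.0)
    return m0, m1


@dataclass
class EquilibriumCurve:
    """Endemic equilibrium tabulated over a grid of mixing levels.

    Columns are in canonical orientation: group 1 resistant, group 2
    sensitive; ``avg = (rho1+rho2)/2`` and ``diff = rho2 - rho1``.
    """

    m: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    positive: np.ndarray
    rates: EffectiveRates | None = None
    mbar: float | None = None
    avg: np.ndarray = field(init=False)
    diff: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.m)
        if not (len(self.rho1) == len(self.rho2) == len(self.positive) == n):
            raise ValidationError("curve columns must share the grid length")
        self.avg = (self.rho1 + self.rho2) / 2.0
        self.diff = self.rho2 - self.rho1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "m": self.m, "rho1": self.rho1, "rho2": self.rho2,
            "avg": self.avg, "diff": self.diff, "positive": self.positive,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EquilibriumCurve":
        return cls(m=df["m"].to_numpy(float), rho1=df["rho1"].to_numpy(float),
                   rho2=df["rho2"].to_numpy(float),
                   positive=df["positive"].to_numpy(bool))


DEFAULT_GRID_SIZE = 201


def default_m_grid(n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def equilibrium_curve(rates: EffectiveRates, m_grid=None,
                      refine_threshold: bool = True) -> EquilibriumCurve:
    """Tabulate the endemic equilibrium over ``m_grid`` (default 201 evenly
    spaced points on [0, 1]).

    When the extinction threshold mbar falls inside the grid range and
    ``refine_threshold`` is set, grid points are inserted at mbar and just
    below it so the extinction of the endemic state is resolved to 1e-6.
    """
    if m_grid is None:
        m_grid = default_m_grid()
    m_grid = np.asarray(m_grid, dtype=float)
    if m_grid.ndim != 1 or len(m_grid) < 1 or np.any(np.diff(m_grid) <= 0):
        raise ValidationError("m_grid must be a strictly increasing 1-D grid")
    if m_grid[0] < 0.0 or m_grid[-1] > 1.0:
        raise ValidationError("m_grid must lie within [0, 1]")

    mbar = mbar_formula(rates)
    if refine_threshold and mbar is not None and m_grid[0] < mbar < m_grid[-1]:
        extra = np.array([mbar - 1e-6, mbar])
        extra = extra[(extra >= m_grid[0]) & (extra <= m_grid[-1])]
        m_grid = np.unique(np.concatenate([m_grid, extra]))

    rho1 = np.empty_like(m_grid)
    rho2 = np.empty_like(m_grid)
    positive = np.empty(len(m_grid), dtype=bool)
    for k, m in enumerate(m_grid):
        try:
            res = solve_equilibrium(rates, float(m))
        except SolverError as exc:
            raise SolverError(f"at m={m}: {exc}") from exc
        rho1[k], rho2[k] = res.state.rho1, res.state.rho2
        positive[k] = res.positive
    return EquilibriumCurve(m=m_grid, rho1=rho1, rho2=rho2,
                            positive=positive, rates=rates, mbar=mbar)
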