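"""State-conditional contagion: both transition rates depend on the partner.

In the plain SIS model only the susceptible-to-infected transition is
contagious. Social applications (peer motivation in classrooms, work-team
productivity) suggest letting *both* transitions depend on the partner's
state. Each group i carries four rates, conditional on the partner being
susceptible (S) or infected (I):

  nu_S    = rate of adopting I when meeting an S partner (background adoption)
  nu_I    = rate of adopting I when meeting an I partner
  delta_I = rate of reverting to S when meeting an I partner
  delta_S = rate of reverting to S when meeting an S partner

with 0 < nu_S < nu_I < 1 and 0 < delta_I < delta_S < 1. Writing
I_i = (1-m)*rho_i + m*rho_j for the probability that a partner is
infected, the mean dynamics are

  drho_i/dt = (1-rho_i)*[nu_I*I_i + nu_S*(1-I_i)]
              - rho_i*[delta_I*I_i + delta_S*(1-I_i)].

Because nu_S > 0 there is no extinction: for every rho_j the per-group
stationarity condition has a unique root in (0, 1), defining a strictly
increasing reaction function. When (nu_I - nu_S) > (delta_S - delta_I)
the reaction function is strictly concave (convex when reversed); in the
concave-concave and convex-convex cases the system has a unique interior
globally asymptotically stable state, found here as the fixed point of the
composed reaction functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .sis_core import (
    IntegrationError,
    PopulationState,
    ValidationError,
    check_mixing_level,
)
from .equilibria import EquilibriumCurve, EquilibriumResult, STABILITY_TOL


@dataclass(frozen=True)
class ConditionalRates:
    """Per-group transition rates conditional on the partner's state."""

    nu_S: float
    nu_I: float
    delta_I: float
    delta_S: float

    def __post_init__(self) -> None:
        if not (0.0 < self.nu_S < self.nu_I < 1.0):
            raise ValidationError(
                f"need 0 < nu_S < nu_I < 1, got ({self.nu_S!r}, {self.nu_I!r})")
        if not (0.0 < self.delta_I < self.delta_S < 1.0):
            raise ValidationError(
                f"need 0 < delta_I < delta_S < 1, got "
                f"({self.delta_I!r}, {self.delta_S!r})")

    @classmethod
    def from_percent(cls, nu_S, nu_I, delta_I, delta_S) -> "ConditionalRates":
        """Build from percentages (e.g. figure captions quoted in %)."""
        return cls(nu_S / 100.0, nu_I / 100.0, delta_I / 100.0, delta_S / 100.0)


@dataclass(frozen=True)
class GeneralModel:
    """Two groups of conditional rates plus a mixing level."""

    group1: ConditionalRates
    group2: ConditionalRates
    m: float

    def __post_init__(self) -> None:
        check_mixing_level(self.m)

    def group(self, i: int) -> ConditionalRates:
        return (self.group1, self.group2)[i - 1]


def exposure(rho_i: float, rho_j: float, m: float) -> float:
    """Probability that a random partner of a group-i individual is
    infected: the convex combination (1-m)*rho_i + m*rho_j."""
    m = check_mixing_level(m)
    for name, v in (("rho_i", rho_i), ("rho_j", rho_j)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
    return (1.0 - m) * rho_i + m * rho_j


def _group_rhs(rho_i: float, rho_j: float, g: ConditionalRates,
               m: float) -> float:
    ii = (1.0 - m) * rho_i + m * rho_j
    gain = (1.0 - rho_i) * (g.nu_I * ii + g.nu_S * (1.0 - ii))
    loss = rho_i * (g.delta_I * ii + g.delta_S * (1.0 - ii))
    return gain - loss


def general_rhs(state, model: GeneralModel) -> np.ndarray:
    """Time derivative (rho1_dot, rho2_dot) of the general model."""
    r1, r2 = float(state[0]), float(state[1])
    return np.array([
        _group_rhs(r1, r2, model.group1, model.m),
        _group_rhs(r2, r1, model.group2, model.m),
    ])


def general_reaction(rho_j: float, group_rates: ConditionalRates,
                     m: float) -> float:
    """Unique stationary fraction of one group given the other's.

    The stationarity condition is a quadratic in rho_i that is positive at
    0 (background adoption nu_S > 0) and negative at 1, so it has exactly
    one root in (0, 1). Solved in closed form with a bracketed fallback.
    """
    m = check_mixing_level(m)
    if not 0.0 <= rho_j <= 1.0:
        raise ValidationError(f"rho_j must lie in [0, 1], got {rho_j!r}")
    g = group_rates
    dn = g.nu_I - g.nu_S          # > 0
    dd = g.delta_I - g.delta_S    # < 0
    alpha = 1.0 - m
    beta = m * rho_j
    a = -alpha * (dn + dd)
    b = dn * alpha - g.nu_S - dn * beta - g.delta_S - dd * beta
    c = g.nu_S + dn * beta        # = f(0) > 0
    if abs(a) < 1e-14:
        return -c / b  # b < 0 since f(1) < 0 and f is affine
    disc = b * b - 4.0 * a * c
    if disc >= 0.0:
        sq = math.sqrt(disc)
        # stable quadratic roots
        q = -0.5 * (b + math.copysign(sq, b))
        roots = [r for r in (q / a, (c / q if q != 0.0 else math.inf))
                 if 0.0 <= r <= 1.0]
        if len(roots) == 1:
            return roots[0]
    # fall back to the guaranteed sign-change bracket
    return brentq(lambda r: _group_rhs(r, rho_j, g, m), 0.0, 1.0,
                  xtol=1e-15, rtol=8.9e-16)


def curvature_class(group_rates: ConditionalRates,
                    tol: float = 1e-12) -> str:
    """Curvature of the group's reaction function in rho_j: 'concave' when
    the contagion spread nu_I - nu_S exceeds the recovery spread
    delta_S - delta_I, 'convex' when it falls short, 'linear' at equality
    (within ``tol``)."""
    margin = ((group_rates.nu_I - group_rates.nu_S)
              - (group_rates.delta_S - group_rates.delta_I))
    if abs(margin) <= tol:
        return "linear"
    return "concave" if margin > 0.0 else "convex"


def _corner_iteration(model: GeneralModel, start: float,
                      tol: float = 1e-14, max_iter: int = 200000) -> float:
    """Monotone fixed-point iteration of the composed reaction map for
    rho2, started from a corner (0 or 1)."""
    r2 = start
    for _ in range(max_iter):
        nxt = general_reaction(
            general_reaction(r2, model.group1, model.m), model.group2, model.m)
        if abs(nxt - r2) < tol:
            return nxt
        r2 = nxt
    raise RuntimeError("corner iteration did not converge")


def general_equilibrium(model: GeneralModel,
                        tol: float = 1e-12,
                        check_uniqueness: bool = True) -> EquilibriumResult:
    """Interior stationary state of the general model.

    The fixed point of h(rho2) = R2(R1(rho2)) is bracketed on [0, 1]
    (h(0) > 0, h(1) < 1) and found by Brent's method. In the
    concave-concave and convex-convex cases it is unique and globally
    stable; for mixed curvature the monotone iterations from both corners
    are compared and a warning is emitted if they disagree (multiple
    equilibria).
    """
    cls1 = curvature_class(model.group1)
    cls2 = curvature_class(model.group2)
    mixed = "linear" not in (cls1, cls2) and cls1 != cls2
    if mixed:
        warnings.warn(
            "mixed concave/convex reaction functions: uniqueness of the "
            "interior state is not guaranteed", RuntimeWarning, stacklevel=2)

    def gap(r2: float) -> float:
        return general_reaction(
            general_reaction(r2, model.group1, model.m),
            model.group2, model.m) - r2

    r2 = brentq(gap, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16)
    r1 = general_reaction(r2, model.group1, model.m)
    residual = float(np.max(np.abs(general_rhs((r1, r2), model))))
    if residual > max(tol, 1e-11):
        raise RuntimeError(f"general equilibrium residual {residual:.2e} "
                           f"exceeds tolerance at m={model.m}")
    if check_uniqueness and mixed:
        lo = _corner_iteration(model, 0.0)
        hi = _corner_iteration(model, 1.0)
        if abs(hi - lo) > 1e-8:
            warnings.warn(
                f"multiple interior states detected: rho2 in "
                f"[{lo:.6f}, {hi:.6f}]", RuntimeWarning, stacklevel=2)
    eig = np.linalg.eigvals(general_jacobian((r1, r2), model))
    return EquilibriumResult(PopulationState(r1, r2), positive=True,
                             residual=residual,
                             stable=bool(np.max(eig.real) <= STABILITY_TOL))


def general_jacobian(state, model: GeneralModel) -> np.ndarray:
    """Jacobian of :func:`general_rhs` at ``state``."""
    r1, r2 = float(state[0]), float(state[1])
    m = model.m
    out = np.empty((2, 2))
    for row, (ri, rj, g) in enumerate(((r1, r2, model.group1),
                                       (r2, r1, model.group2))):
        ii = (1.0 - m) * ri + m * rj
        dn = g.nu_I - g.nu_S
        dd = g.delta_I - g.delta_S
        d_own = (-(g.nu_I * ii + g.nu_S * (1.0 - ii))
                 + (1.0 - ri) * dn * (1.0 - m)
                 - (g.delta_I * ii + g.delta_S * (1.0 - ii))
                 - ri * dd * (1.0 - m))
        d_other = (1.0 - ri) * dn * m - ri * dd * m
        out[row, row] = d_own
        out[row, 1 - row] = d_other
    return out


def general_curve(group1: ConditionalRates, group2: ConditionalRates,
                  m_grid=None) -> EquilibriumCurve:
    """Tabulate the interior state over a grid of mixing levels.

    Returns the same curve container as the SIS model, so the regime
    analyses (monotonicity detection, Pareto sets, optimal mixing) apply
    unchanged.
    """
    if m_grid is None:
        m_grid = np.linspace(0.0, 1.0, 201)
    m_grid = np.asarray(m_grid, dtype=float)
    if m_grid.ndim != 1 or np.any(np.diff(m_grid) <= 0):
        raise ValidationError("m_grid must be a strictly increasing 1-D grid")
    rho1 = np.empty_like(m_grid)
    rho2 = np.empty_like(m_grid)
    for k, m in enumerate(m_grid):
        res = general_equilibrium(GeneralModel(group1, group2, float(m)),
                                  check_uniqueness=False)
        rho1[k], rho2[k] = res.state.rho1, res.state.rho2
    return EquilibriumCurve(m=m_grid, rho1=rho1, rho2=rho2,
                            positive=np.ones(len(m_grid), dtype=bool))


def integrate_general(state0, model: GeneralModel, tol: float = 1e-10,
                      max_horizon: float = 1e6):
    """Integrate the general mean dynamics to stationarity (adaptive
    horizon, as in :func:`mixsis.sis_core.integrate`)."""
    from scipy.integrate import solve_ivp

    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (2,) or np.any(y0 < 0.0) or np.any(y0 > 1.0):
        raise ValidationError("initial state must be a pair in [0, 1]^2")

    def rhs(_t, y):
        return general_rhs(y, model)

    t0, y, span = 0.0, y0.copy(), 50.0
    while True:
        sol = solve_ivp(rhs, (t0, t0 + span), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"integration failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, 1.0)
        t0 = float(sol.t[-1])
        if float(np.max(np.abs(rhs(t0, y)))) < tol or t0 >= max_horizon:
            return PopulationState(float(y[0]), float(y[1]))
        span *= 2.0
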