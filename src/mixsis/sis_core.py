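"""Mean-field core of the two-group SIS model with a tunable mixing level.

A population is split into two groups of equal size. In each period every
individual interacts with another individual with probability ``p``; the
partner belongs to the *other* group with probability ``m`` (the mixing
level) and to the individual's own group otherwise. A susceptible individual
of group ``i`` that meets an infected partner becomes infected with
probability ``upsilon_i``; infected individuals recover with probability
``delta_i``. The fraction of infected individuals ``rho_i`` in each group
then evolves, in the mean-field (large-population) limit, according to

    drho_i/dt = delta_i * [ lambda_i * (1 - rho_i) * (m*rho_j + (1-m)*rho_i)
                            - rho_i ],

where ``lambda_i = p * upsilon_i / delta_i`` is the *effective adoption
rate* of group ``i``. Equilibria and long-run behaviour depend only on
``(lambda1, lambda2, m)``; the recovery rates merely rescale time.

All parameters may be read either as per-period probabilities or as
continuous-time rates; this module treats them uniformly as rates, which
leaves equilibria unchanged.

Group orientation is canonicalised so that ``lambda1 <= lambda2``: group 2
is the *sensitive* group and group 1 the *resistant* group. The
``EffectiveRates.swapped`` flag records whether the caller's group order
was flipped, so user-facing output can be restored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


class ValidationError(ValueError):
    """A model parameter lies outside its admissible range."""


class IntegrationError(RuntimeError):
    """The ODE integration produced a non-finite or divergent state."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def check_mixing_level(m: float) -> float:
    """Validate a mixing level m, the expected fraction of between-group
    interactions: m=0 is full segregation, m=1 the bipartite case."""
    m = float(m)
    _require(math.isfinite(m) and 0.0 <= m <= 1.0,
             f"mixing level m must lie in [0, 1], got {m!r}")
    return m


@dataclass(frozen=True)
class SISParameters:
    """Raw per-period SIS parameters.

    p : interaction probability (or rate) per period, in (0, 1].
    upsilon1, upsilon2 : per-contact infection probabilities, in (0, 1).
    delta1, delta2 : recovery probabilities, in (0, 1).
    """

    p: float
    upsilon1: float
    upsilon2: float
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        _require(0.0 < self.p <= 1.0, f"p must be in (0, 1], got {self.p!r}")
        for name in ("upsilon1", "upsilon2", "delta1", "delta2"):
            v = getattr(self, name)
            _require(0.0 < v < 1.0, f"{name} must be in (0, 1), got {v!r}")

    @property
    def deltas(self) -> tuple[float, float]:
        return (self.delta1, self.delta2)


@dataclass(frozen=True)
class EffectiveRates:
    """The pair of effective adoption rates lambda_i = p*upsilon_i/delta_i.

    Stored in canonical orientation ``lambda1 <= lambda2`` (group 2
    sensitive); ``swapped`` records whether the caller's group order was
    flipped to achieve this. Build from arbitrary order with
    :meth:`from_pair`.
    """

    lambda1: float
    lambda2: float
    swapped: bool = False

    def __post_init__(self) -> None:
        _require(self.lambda1 > 0 and self.lambda2 > 0,
                 f"effective rates must be positive, got "
                 f"({self.lambda1!r}, {self.lambda2!r})")
        _require(self.lambda1 <= self.lambda2,
                 "EffectiveRates stores the canonical orientation "
                 "lambda1 <= lambda2; use EffectiveRates.from_pair")

    @classmethod
    def from_pair(cls, lambda1: float, lambda2: float) -> "EffectiveRates":
        """Canonicalise an arbitrary (lambda1, lambda2) pair."""
        _require(float(lambda1) > 0 and float(lambda2) > 0,
                 f"effective rates must be positive, got "
                 f"({lambda1!r}, {lambda2!r})")
        if lambda1 > lambda2:
            return cls(float(lambda2), float(lambda1), swapped=True)
        return cls(float(lambda1), float(lambda2), swapped=False)

    @property
    def product(self) -> float:
        return self.lambda1 * self.lambda2

    def user_order(self, x1, x2) -> tuple:
        """Restore a per-group pair to the caller's original group order."""
        return (x2, x1) if self.swapped else (x1, x2)


def effective_rates(params: SISParameters) -> EffectiveRates:
    """Reduce raw (p, upsilon_i, delta_i) to effective adoption rates."""
    return EffectiveRates.from_pair(
        params.p * params.upsilon1 / params.delta1,
        params.p * params.upsilon2 / params.delta2,
    )


@dataclass(frozen=True)
class PopulationState:
    """Infected fractions (rho1, rho2) of the two groups."""

    rho1: float
    rho2: float

    _TOL = 1e-7

    def __post_init__(self) -> None:
        for name in ("rho1", "rho2"):
            v = getattr(self, name)
            _require(-self._TOL <= v <= 1.0 + self._TOL,
                     f"{name} must lie in [0, 1], got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.clip(np.array([self.rho1, self.rho2], dtype=float), 0.0, 1.0)


def sis_rhs(state, rates: EffectiveRates, m: float,
            deltas: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Time derivative (rho1_dot, rho2_dot) of the two-group SIS system.

    With ``deltas`` omitted the recovery rates are set to 1, which only
    rescales time and leaves equilibria unchanged.
    """
    m = check_mixing_level(m)
    r1, r2 = float(state[0]), float(state[1])
    d1, d2 = deltas
    f1 = d1 * (rates.lambda1 * (1.0 - r1) * (m * r2 + (1.0 - m) * r1) - r1)
    f2 = d2 * (rates.lambda2 * (1.0 - r2) * (m * r1 + (1.0 - m) * r2) - r2)
    return np.array([f1, f2])


def sis_jacobian(state, rates: EffectiveRates, m: float,
                 deltas: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Jacobian of :func:`sis_rhs` at ``state``."""
    r1, r2 = float(state[0]), float(state[1])
    l1, l2 = rates.lambda1, rates.lambda2
    d1, d2 = deltas
    return np.array([
        [d1 * (l1 * ((1.0 - r1) * (1.0 - m) - (m * r2 + (1.0 - m) * r1)) - 1.0),
         d1 * l1 * (1.0 - r1) * m],
        [d2 * l2 * (1.0 - r2) * m,
         d2 * (l2 * ((1.0 - r2) * (1.0 - m) - (m * r1 + (1.0 - m) * r2)) - 1.0)],
    ])


@dataclass
class Trajectory:
    """Numerical solution of the mean dynamics: times and states."""

    t: np.ndarray
    rho: np.ndarray  # shape (n, 2)
    residual: float  # max |rho_dot| at the final state

    @property
    def final(self) -> PopulationState:
        return PopulationState(float(self.rho[-1, 0]), float(self.rho[-1, 1]))


_CLIP_WARN = 1e-9


def _clip_states(y: np.ndarray) -> np.ndarray:
    overshoot = max(float(np.max(y - 1.0, initial=0.0)),
                    float(np.max(-y, initial=0.0)))
    if overshoot > _CLIP_WARN:
        warnings.warn(f"integration left [0,1]^2 by {overshoot:.2e}; clipped",
                      RuntimeWarning, stacklevel=3)
    return np.clip(y, 0.0, 1.0)


def integrate(state0, rates: EffectiveRates, m: float,
              horizon: float | None = None, tol: float = 1e-10,
              deltas: tuple[float, float] = (1.0, 1.0),
              max_horizon: float = 1e6) -> Trajectory:
    """Integrate the mean dynamics from ``state0``.

    If ``horizon`` is given, integrate exactly that long. Otherwise extend
    the integration in doubling chunks until the stationarity residual
    ``max_i |rho_i_dot|`` drops below ``tol`` (or ``max_horizon`` is hit).
    """
    m = check_mixing_level(m)
    y0 = np.asarray(state0, dtype=float)
    _require(y0.shape == (2,) and np.all(y0 >= 0.0) and np.all(y0 <= 1.0),
             "initial state must be a pair in [0, 1]^2")

    def rhs(_t, y):
        return sis_rhs(y, rates, m, deltas)

    ts = [np.array([0.0])]
    ys = [y0[None, :]]
    t0, y = 0.0, y0.copy()
    span = horizon if horizon is not None else 50.0
    while True:
        sol = solve_ivp(rhs, (t0, t0 + span), y, method="LSODA",
                        rtol=1e-10, atol=1e-12, dense_output=False)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(f"integration failed at t={t0}: {sol.message}")
        yy = _clip_states(sol.y.T)
        ts.append(sol.t[1:])
        ys.append(yy[1:])
        t0, y = float(sol.t[-1]), yy[-1]
        residual = float(np.max(np.abs(rhs(t0, y))))
        if horizon is not None or residual < tol or t0 >= max_horizon:
            break
        span *= 2.0
    return Trajectory(np.concatenate(ts), np.vstack(ys),
                      float(np.max(np.abs(rhs(t0, y)))))


@dataclass(frozen=True)
class OriginStabilityReport:
    """Stability of the no-diffusion state (0, 0).

    ``mbar`` is the mixing threshold above which (0, 0) is stable; it is
    defined only in the regime lambda2 > 1 >= lambda1*lambda2 and equals 1
    exactly when lambda1*lambda2 = 1. ``origin_stable`` and
    ``leading_eigenvalue`` refer to the mixing level supplied to
    :func:`mixing_threshold` (None if none was supplied).
    """

    mbar: float | None
    origin_stable: bool | None = None
    leading_eigenvalue: float | None = None


def leading_origin_eigenvalue(rates: EffectiveRates, m: float,
                              deltas: tuple[float, float] = (1.0, 1.0)) -> float:
    """Largest eigenvalue of the linearisation at (0, 0).

    The Jacobian at the origin is Metzler (non-negative off-diagonals), so
    its leading eigenvalue is real; its sign decides local stability of the
    no-diffusion state.
    """
    m = check_mixing_level(m)
    j = sis_jacobian((0.0, 0.0), rates, m, deltas)
    a, b, c, d = j[0, 0], j[0, 1], j[1, 0], j[1, 1]
    disc = (a - d) ** 2 + 4.0 * b * c
    return 0.5 * ((a + d) + math.sqrt(disc))


def mbar_formula(rates: EffectiveRates) -> float | None:
    """Closed-form mixing threshold of the no-diffusion state.

    Returns ``1 - (1 - l1*l2) / (l1 + l2 - 2*l1*l2)`` in the regime
    ``lambda2 > 1 >= lambda1*lambda2``; None elsewhere (the origin is then
    stable for every m if lambda2 <= 1, unstable for every m if
    lambda1*lambda2 > 1).
    """
    l1, l2 = rates.lambda1, rates.lambda2
    prod = l1 * l2
    if l2 <= 1.0 or prod > 1.0:
        return None
    denom = l1 + l2 - 2.0 * prod
    # AM-GM gives l1 + l2 >= 2*sqrt(prod) >= 2*prod when prod <= 1, strict
    # here because l2 > 1 > l1; so the denominator cannot vanish.
    assert denom > 0.0, "degenerate threshold denominator in admissible region"
    return 1.0 - (1.0 - prod) / denom


def mixing_threshold(rates: EffectiveRates,
                     m: float | None = None) -> OriginStabilityReport:
    """Report the mixing threshold and, if ``m`` is given, origin stability
    at that mixing level (via the leading eigenvalue of the linearisation)."""
    mbar = mbar_formula(rates)
    if m is None:
        return OriginStabilityReport(mbar=mbar)
    lam = leading_origin_eigenvalue(rates, m)
    return OriginStabilityReport(mbar=mbar, origin_stable=bool(lam <= 0.0),
                                 leading_eigenvalue=lam)


def threshold_by_bisection(rates: EffectiveRates, tol: float = 1e-12) -> float:
    """Locate the mixing threshold numerically.

    Bisects m on the sign of the leading origin eigenvalue, independent of
    the closed-form expression; valid in the regime
    lambda2 > 1 >= lambda1*lambda2, where the origin is unstable at m=0 and
    stable at m=1.
    """
    _require(rates.lambda2 > 1.0 >= rates.product,
             "threshold bisection requires lambda2 > 1 >= lambda1*lambda2")
    lo, hi = 0.0, 1.0
    if leading_origin_eigenvalue(rates, 1.0) > 0.0:  # prod == 1 edge
        return 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if leading_origin_eigenvalue(rates, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
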