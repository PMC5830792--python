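"""Qualitative regimes of the (lambda1, lambda2) plane and mixing policy.

With the canonical orientation lambda1 <= lambda2, the plane of effective
adoption rates splits into five regions by how the endemic equilibrium
responds to the mixing level m:

  A : lambda2 <= 1 — no diffusion at any m.
  B : lambda1*lambda2 <= 1 < lambda2 — endemic only for m below the
      threshold mbar < 1; resistant-group level has an interior maximum;
      the average is decreasing.
  C : endemic for all m; resistant-group level non-monotonic (interior
      maximum); average non-monotonic with an interior maximum, minimised
      at m=1.
  D : endemic for all m; resistant-group level increasing; average still
      has an interior maximum, minimised at m=0.
  E : lambda1^(3/4)*(lambda2+1) >= lambda2^(3/4)*(lambda1+1) — every level
      (resistant, sensitive, average) is monotone in m; requires
      lambda2 > 3.

The C/D boundary has the closed-form candidate
lambda1 = sqrt(lambda2)/(lambda2 - sqrt(lambda2) + 1); a numeric
monotonicity scan of the resistant-group curve is authoritative when the
two disagree.

The module also detects monotonicity patterns of equilibrium curves,
computes Pareto-dominated sets of mixing levels (levels for which some
other level is weakly better for both groups and strictly better for one)
and optimises m for simple planner objectives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sis_core import EffectiveRates, ValidationError, mbar_formula
from .equilibria import EquilibriumCurve, equilibrium_curve

BOUNDARY_TOL = 1e-9
MONOTONE_TOL = 1e-7


@dataclass(frozen=True)
class RegionLabel:
    label: str  # one of A..E
    boundary_flags: tuple[str, ...]  # defining inequalities near equality


def cd_boundary_lambda1(lambda2: float) -> float:
    """Closed-form candidate for the C/D boundary at a given lambda2."""
    s = math.sqrt(lambda2)
    return s / (lambda2 - s + 1.0)


def e_condition_margin(rates: EffectiveRates) -> float:
    """Margin of the region-E inequality; >= 0 means E.

    The inequality lambda1^(3/4)*(lambda2+1) >= lambda2^(3/4)*(lambda1+1)
    compares g(l) = l^(3/4)/(l+1) between the groups; g peaks at l=3, which
    is why region E needs lambda2 > 3.
    """
    l1, l2 = rates.lambda1, rates.lambda2
    return l1 ** 0.75 * (l2 + 1.0) - l2 ** 0.75 * (l1 + 1.0)


def classify_region(rates: EffectiveRates, tol: float = BOUNDARY_TOL,
                    scan_grid_size: int = 101) -> RegionLabel:
    """Assign a (lambda1, lambda2) pair to region A, B, C, D or E.

    Precedence A -> B -> E -> C -> D for determinism at boundaries. The
    C/D split is decided by a numeric monotonicity scan of the
    resistant-group equilibrium curve, with the closed-form boundary used
    only as a cross-check.
    """
    l1, l2 = rates.lambda1, rates.lambda2
    flags = []
    if abs(l2 - 1.0) <= tol:
        flags.append("lambda2=1")
    if abs(rates.product - 1.0) <= tol:
        flags.append("lambda1*lambda2=1")
    margin = e_condition_margin(rates)
    if abs(margin) <= tol:
        flags.append("E-boundary")
    if abs(l1 - cd_boundary_lambda1(l2)) <= tol:
        flags.append("C/D-boundary")
    flags = tuple(flags)

    if l2 <= 1.0 + tol:
        return RegionLabel("A", flags)
    if rates.product <= 1.0 + tol:
        return RegionLabel("B", flags)
    if margin >= -tol:
        return RegionLabel("E", flags)
    curve = equilibrium_curve(rates, np.linspace(0.0, 1.0, scan_grid_size))
    verdict = detect_monotonicity(curve.rho1)
    if verdict.pattern == "interior_max":
        return RegionLabel("C", flags)
    return RegionLabel("D", flags)


_PATTERNS = ("increasing", "decreasing", "interior_max", "interior_min",
             "constant")


@dataclass(frozen=True)
class MonotonicityVerdict:
    pattern: str
    argmax_index: int | None = None  # grid index of the interior extremum
    arg_m: float | None = None  # refined m location when a grid was given


def _refine_extremum(m: np.ndarray, v: np.ndarray, k: int) -> float:
    """Parabolic refinement of a grid extremum at index k."""
    if k <= 0 or k >= len(v) - 1:
        return float(m[k])
    x0, x1, x2 = m[k - 1], m[k], m[k + 1]
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = (x0 - x1) * (y1 - y2) - (x1 - x2) * (y0 - y1)
    if denom == 0.0:
        return float(x1)
    num = (x0 * x0 - x1 * x1) * (y1 - y2) - (x1 * x1 - x2 * x2) * (y0 - y1)
    return float(np.clip(0.5 * num / denom, x0, x2))


def detect_monotonicity(values, tol: float = MONOTONE_TOL,
                        m_grid=None) -> MonotonicityVerdict:
    """Classify a curve sampled on an ordered grid as increasing,
    decreasing, constant, or unimodal with one interior extremum.

    Finite differences below ``tol`` in magnitude are treated as noise
    (flat). More than one significant sign change means the curve is not
    unimodal and raises ValueError.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValidationError("need a 1-D curve with at least 3 points")
    d = np.diff(v)
    signs = np.sign(d)
    signs[np.abs(d) <= tol] = 0.0
    sig = signs[signs != 0.0]
    if len(sig) == 0:
        return MonotonicityVerdict("constant")
    changes = np.nonzero(np.diff(sig) != 0.0)[0]
    if len(changes) == 0:
        return MonotonicityVerdict("increasing" if sig[0] > 0 else "decreasing")
    if len(changes) > 1:
        raise ValidationError("curve is not unimodal at the given tolerance")
    if sig[0] > 0:  # rises then falls
        k = int(np.argmax(v))
        arg = None if m_grid is None else _refine_extremum(
            np.asarray(m_grid, float), v, k)
        return MonotonicityVerdict("interior_max", argmax_index=k, arg_m=arg)
    k = int(np.argmin(v))
    arg = None if m_grid is None else _refine_extremum(
        np.asarray(m_grid, float), v, k)
    return MonotonicityVerdict("interior_min", argmax_index=k, arg_m=arg)


@dataclass(frozen=True)
class ParetoReport:
    """Mixing levels Pareto-dominated by some other level on the grid.

    ``orientation`` says whether infection is undesirable (lower is
    better, the default) or desirable. ``dominated_intervals`` merges
    contiguous dominated grid points into (m_lo, m_hi) intervals, each with
    a witness m' that dominates every point of the interval's interior
    representative.
    """

    orientation: str  # "undesirable" | "desirable"
    dominated_mask: np.ndarray
    dominated_intervals: list[tuple[float, float]]
    witnesses: list[float]


def pareto_inefficient_set(curve: EquilibriumCurve,
                           undesirable: bool = True,
                           tol: float = BOUNDARY_TOL) -> ParetoReport:
    """Find grid mixing levels dominated by another grid level.

    A level m is dominated by m' when both groups are weakly better off at
    m' (within ``tol``) and at least one is strictly better (beyond
    ``tol``).
    """
    sign = 1.0 if undesirable else -1.0  # minimise if undesirable
    x1 = sign * curve.rho1
    x2 = sign * curve.rho2
    # improvement[i, j] > 0 where j is better than i for that group
    imp1 = x1[:, None] - x1[None, :]
    imp2 = x2[:, None] - x2[None, :]
    weak = (imp1 >= -tol) & (imp2 >= -tol)
    strict = (imp1 > tol) | (imp2 > tol)
    dominates = weak & strict
    dominated = dominates.any(axis=1)

    intervals: list[tuple[float, float]] = []
    witnesses: list[float] = []
    m = curve.m
    i = 0
    n = len(m)
    while i < n:
        if not dominated[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and dominated[j + 1]:
            j += 1
        mid = (i + j) // 2
        # prefer a witness that dominates the whole interval; fall back to
        # one dominating its midpoint
        common = np.where(dominates[i:j + 1].all(axis=0))[0]
        cand = common if len(common) else np.where(dominates[mid])[0]
        best = cand[np.argmax(imp1[mid, cand] + imp2[mid, cand])]
        intervals.append((float(m[i]), float(m[j])))
        witnesses.append(float(m[best]))
        i = j + 1
    return ParetoReport("undesirable" if undesirable else "desirable",
                        dominated, intervals, witnesses)


OBJECTIVES = ("min_avg", "max_avg", "min_diff")


def optimal_mixing(curve: EquilibriumCurve, objective: str) -> float:
    """Optimal mixing level on the curve for a planner objective.

    ``min_avg``/``max_avg`` act on the average infection level,
    ``min_diff`` on the between-group gap rho2 - rho1. Grid optimisation
    with parabolic refinement at interior optima; ties resolved to the
    smallest m.
    """
    if objective not in OBJECTIVES:
        raise ValidationError(f"objective must be one of {OBJECTIVES}")
    if objective == "min_diff":
        v = curve.diff
        mode = "min"
    else:
        v = curve.avg
        mode = "min" if objective == "min_avg" else "max"
    vv = v if mode == "max" else -v
    best = float(np.max(vv))
    k = int(np.argmax(vv >= best - BOUNDARY_TOL))  # smallest optimiser
    if 0 < k < len(vv) - 1:
        return _refine_extremum(curve.m, vv, k)
    return float(curve.m[k])
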