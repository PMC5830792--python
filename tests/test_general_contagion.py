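"""Unit tests for the state-conditional contagion model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from mixsis import (
    ConditionalRates,
    GeneralModel,
    ValidationError,
    curvature_class,
    detect_monotonicity,
    exposure,
    general_curve,
    general_equilibrium,
    general_reaction,
    general_rhs,
    integrate_general,
    pareto_inefficient_set,
)


def rate_bundles():
    """Strategy for valid conditional-rate bundles."""
    eps = 1e-3

    @st.composite
    def build(draw):
        nu_s = draw(st.floats(eps, 0.9))
        nu_i = draw(st.floats(nu_s + eps, 0.999))
        d_i = draw(st.floats(eps, 0.9))
        d_s = draw(st.floats(d_i + eps, 0.999))
        return ConditionalRates(nu_s, nu_i, d_i, d_s)

    return build()


class TestConditionalRates:
    @pytest.mark.parametrize("args", [
        (0.2, 0.1, 0.1, 0.3),   # nu_I < nu_S
        (0.1, 0.2, 0.4, 0.3),   # delta_S < delta_I
        (0.0, 0.2, 0.1, 0.3),   # boundary value
        (0.1, 0.1, 0.1, 0.3),   # equal adoption rates
    ])
    def test_ordering_enforced(self, args):
        with pytest.raises(ValidationError):
            ConditionalRates(*args)

    def test_percent_constructor(self):
        g = ConditionalRates.from_percent(1, 15, 60, 70)
        assert g == ConditionalRates(0.01, 0.15, 0.60, 0.70)


@pytest.mark.parametrize("m, expected", [(0.0, 0.2), (1.0, 0.4), (0.5, 0.3)])
def test_exposure_is_convex_combination(m, expected):
    assert exposure(0.2, 0.4, m) == pytest.approx(expected)


class TestGeneralRHS:
    @given(rate_bundles(), rate_bundles(),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_boundary_signs(self, g1, g2, m, rho_j):
        # inflow at rho_i = 0 (background adoption), outflow at rho_i = 1
        model = GeneralModel(g1, g2, m)
        assert general_rhs((0.0, rho_j), model)[0] > 0.0
        assert general_rhs((1.0, rho_j), model)[0] < 0.0

    def test_boundary_values_match_closed_forms(self):
        g1 = ConditionalRates.from_percent(1, 15, 60, 70)
        g2 = ConditionalRates.from_percent(1, 80, 1, 20)
        m, rho2 = 0.4, 0.3
        model = GeneralModel(g1, g2, m)
        up = general_rhs((0.0, rho2), model)[0]
        assert up == pytest.approx(g1.nu_S + m * rho2 * (g1.nu_I - g1.nu_S))
        down = general_rhs((1.0, rho2), model)[0]
        assert down == pytest.approx(
            -(g1.delta_I + m * (1 - rho2) * (g1.delta_S - g1.delta_I)))

    def test_near_uniform_rates_balance_at_logistic_point(self):
        # as the conditional spread vanishes, the stationary point tends to
        # nu / (nu + delta)
        eps = 1e-9
        nu, delta = 0.3, 0.2
        g = ConditionalRates(nu - eps, nu, delta, delta + eps)
        model = GeneralModel(g, g, 0.5)
        rho = nu / (nu + delta)
        assert general_rhs((rho, rho), model) == pytest.approx((0, 0), abs=1e-8)


class TestGeneralReaction:
    def test_against_bracketing_oracle(self):
        # group rates (1, 15, 60, 70)% at m=0: root of
        # (1-r)(0.15 r + 0.01 (1-r)) = r (0.60 r + 0.70 (1-r))
        g = ConditionalRates.from_percent(1, 15, 60, 70)

        def stationarity(r):
            return (1 - r) * (0.15 * r + 0.01 * (1 - r)) \
                - r * (0.60 * r + 0.70 * (1 - r))

        oracle = brentq(stationarity, 0.0, 1.0, xtol=1e-14)
        for rho_j in (0.0, 0.5, 1.0):  # m=0: no dependence on the other group
            assert general_reaction(rho_j, g, 0.0) == pytest.approx(
                oracle, abs=1e-12)

    def test_strictly_increasing_in_other_group(self):
        g2 = ConditionalRates.from_percent(1, 80, 1, 20)
        lo = general_reaction(0.2, g2, 0.5)
        hi = general_reaction(0.6, g2, 0.5)
        assert hi > lo

    @given(rate_bundles(), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_output_strictly_interior_and_stationary(self, g, rho_j, m):
        r = general_reaction(rho_j, g, m)
        assert 0.0 < r < 1.0
        model = GeneralModel(g, g, m)
        assert abs(general_rhs((r, rho_j), model)[0]) < 1e-9


class TestCurvature:
    def test_showcase_groups_are_concave(self):
        assert curvature_class(ConditionalRates.from_percent(1, 15, 60, 70)) \
            == "concave"
        assert curvature_class(ConditionalRates.from_percent(1, 80, 1, 20)) \
            == "concave"

    def test_convex_and_linear(self):
        assert curvature_class(ConditionalRates(0.1, 0.2, 0.2, 0.5)) == "convex"
        assert curvature_class(ConditionalRates(0.1, 0.3, 0.2, 0.4)) == "linear"


class TestGeneralEquilibrium:
    def test_symmetric_groups_equalise(self):
        g = ConditionalRates(0.05, 0.4, 0.1, 0.3)
        for m in (0.0, 0.5, 1.0):
            res = general_equilibrium(GeneralModel(g, g, m))
            assert res.state.rho1 == pytest.approx(res.state.rho2, abs=1e-12)

    def test_matches_ode_long_run(self, conditional_groups):
        g1, g2 = conditional_groups
        for m in (0.0, 0.25, 0.6, 1.0):
            model = GeneralModel(g1, g2, m)
            fixed = general_equilibrium(model)
            ode = integrate_general((0.5, 0.5), model, tol=1e-12)
            assert fixed.state.rho1 == pytest.approx(ode.rho1, abs=1e-6)
            assert fixed.state.rho2 == pytest.approx(ode.rho2, abs=1e-6)

    def test_corner_starts_agree_in_concave_case(self, conditional_groups):
        from mixsis.general_contagion import _corner_iteration

        g1, g2 = conditional_groups
        model = GeneralModel(g1, g2, 0.5)
        assert abs(_corner_iteration(model, 0.0)
                   - _corner_iteration(model, 1.0)) < 1e-8

    def test_stable_and_interior(self, conditional_groups):
        res = general_equilibrium(GeneralModel(*conditional_groups, 0.3))
        assert res.positive and res.stable
        assert 0 < res.state.rho1 < 1 and 0 < res.state.rho2 < 1


class TestGeneralCurve:
    def test_showcase_curve_nonmonotone_with_dominated_levels(
            self, conditional_groups):
        curve = general_curve(*conditional_groups)
        verdict = detect_monotonicity(curve.rho1)
        assert verdict.pattern == "interior_max"
        rep = pareto_inefficient_set(curve)
        assert rep.dominated_intervals
        # sensitive group still only loses from mixing
        assert detect_monotonicity(curve.rho2).pattern == "decreasing"

    def test_no_extinction_anywhere(self, conditional_groups):
        curve = general_curve(*conditional_groups, np.linspace(0, 1, 21))
        assert np.all(curve.rho1 > 0) and np.all(curve.rho2 < 1)
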