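"""Unit tests for parameterisation, dynamics and the origin threshold."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mixsis import (
    EffectiveRates,
    SISParameters,
    ValidationError,
    effective_rates,
    integrate,
    leading_origin_eigenvalue,
    mbar_formula,
    mixing_threshold,
    sis_jacobian,
    sis_rhs,
    threshold_by_bisection,
)


@pytest.mark.parametrize("params, expected", [
    ((1.0, 0.5, 0.5, 0.25, 0.5), (1.0, 2.0)),
    ((0.5, 0.3, 0.7, 0.3, 0.7), (0.5, 0.5)),
    ((1.0, 0.11, 0.4, 0.2, 0.2), (0.55, 2.0)),
])
def test_effective_rates_formula(params, expected):
    p, u1, u2, d1, d2 = params
    rates = effective_rates(SISParameters(p, u1, u2, d1, d2))
    assert rates.lambda1 == pytest.approx(expected[0])
    assert rates.lambda2 == pytest.approx(expected[1])


def test_effective_rates_canonical_swap():
    rates = effective_rates(SISParameters(1.0, 0.4, 0.11, 0.2, 0.2))
    assert rates.swapped
    assert (rates.lambda1, rates.lambda2) == pytest.approx((0.55, 2.0))
    assert rates.user_order("r", "s") == ("s", "r")


@pytest.mark.parametrize("bad", [
    dict(p=0.0), dict(upsilon1=-0.1), dict(delta2=0.0), dict(p=1.5),
    dict(upsilon2=1.0),
])
def test_invalid_parameters_rejected(bad):
    kwargs = dict(p=1.0, upsilon1=0.3, upsilon2=0.4, delta1=0.2, delta2=0.2)
    kwargs.update(bad)
    with pytest.raises(ValidationError):
        SISParameters(**kwargs)


def test_rates_must_be_positive():
    with pytest.raises(ValidationError):
        EffectiveRates.from_pair(-1.0, 2.0)


class TestRHS:
    def test_origin_is_stationary(self):
        assert sis_rhs((0.0, 0.0), EffectiveRates(0.7, 3.0), 0.4) == pytest.approx((0, 0))

    def test_isolated_group_equilibrium(self):
        # m=0 decouples the groups; rho = 1 - 1/lambda is stationary
        out = sis_rhs((0.5, 0.8), EffectiveRates(2.0, 5.0), 0.0)
        assert out == pytest.approx((0.0, 0.0), abs=1e-15)

    def test_hand_evaluated_value(self):
        # lambda=(0.55,2), m=0.5, rho=(0.2,0.4):
        # rho1_dot = 0.55*0.8*0.3 - 0.2 = -0.068
        # rho2_dot = 2*0.6*0.3 - 0.4 = -0.04
        out = sis_rhs((0.2, 0.4), EffectiveRates(0.55, 2.0), 0.5)
        assert out == pytest.approx((-0.068, -0.04))

    def test_delta_scaling(self):
        rates = EffectiveRates(0.55, 2.0)
        base = sis_rhs((0.2, 0.4), rates, 0.5)
        scaled = sis_rhs((0.2, 0.4), rates, 0.5, deltas=(0.25, 0.5))
        assert scaled == pytest.approx((0.25 * base[0], 0.5 * base[1]))

    def test_invalid_mixing_level(self):
        with pytest.raises(ValidationError):
            sis_rhs((0.2, 0.4), EffectiveRates(1.0, 2.0), 1.5)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_forward_invariance_of_unit_box(self, l1, l2, m, rho_other):
        # no flow out of [0,1]^2: inflow at rho_i=0, outflow at rho_i=1
        rates = EffectiveRates.from_pair(l1, l2)
        assert sis_rhs((0.0, rho_other), rates, m)[0] >= 0.0
        assert sis_rhs((1.0, rho_other), rates, m)[0] <= 0.0
        assert sis_rhs((rho_other, 0.0), rates, m)[1] >= 0.0
        assert sis_rhs((rho_other, 1.0), rates, m)[1] <= 0.0


def test_jacobian_matches_finite_differences():
    rates = EffectiveRates(0.55, 2.0)
    state = np.array([0.2, 0.4])
    h = 1e-7
    jac = sis_jacobian(state, rates, 0.3, deltas=(0.7, 1.3))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        fd = (sis_rhs(state + e, rates, 0.3, deltas=(0.7, 1.3))
              - sis_rhs(state - e, rates, 0.3, deltas=(0.7, 1.3))) / (2 * h)
        assert jac[:, j] == pytest.approx(fd, abs=1e-6)


class TestIntegrate:
    def test_origin_stays_put(self):
        traj = integrate((0.0, 0.0), EffectiveRates(2.0, 5.0), 0.5, horizon=100.0)
        assert traj.final.rho1 == 0.0 and traj.final.rho2 == 0.0

    def test_bipartite_long_run_matches_closed_form(self):
        traj = integrate((0.01, 0.01), EffectiveRates(2.0, 5.0), 1.0)
        assert traj.final.rho1 == pytest.approx(0.6, abs=1e-8)
        assert traj.final.rho2 == pytest.approx(0.75, abs=1e-8)

    def test_subcritical_sensitive_group_goes_extinct(self):
        traj = integrate((0.9, 0.9), EffectiveRates(0.5, 0.8), 0.3)
        assert traj.final.rho1 == pytest.approx(0.0, abs=1e-8)
        assert traj.final.rho2 == pytest.approx(0.0, abs=1e-8)

    def test_equilibrium_invariant_to_recovery_rescaling(self):
        rates = EffectiveRates(0.55, 2.0)
        a = integrate((0.3, 0.3), rates, 0.4, deltas=(1.0, 1.0))
        b = integrate((0.3, 0.3), rates, 0.4, deltas=(0.2, 0.9))
        assert a.final.rho1 == pytest.approx(b.final.rho1, abs=1e-8)
        assert a.final.rho2 == pytest.approx(b.final.rho2, abs=1e-8)


class TestMixingThreshold:
    def test_unit_product_gives_threshold_one(self):
        assert mbar_formula(EffectiveRates(0.5, 2.0)) == 1.0

    @pytest.mark.parametrize("rates, expected", [
        (EffectiveRates(0.25, 2.0), 0.6),
        (EffectiveRates(0.3, 2.0), 7.0 / 11.0),
    ])
    def test_formula_values(self, rates, expected):
        assert mbar_formula(rates) == pytest.approx(expected, abs=1e-12)
        assert threshold_by_bisection(rates) == pytest.approx(expected, abs=1e-9)

    def test_absent_outside_regime(self):
        assert mixing_threshold(EffectiveRates(0.5, 0.9)).mbar is None
        assert mixing_threshold(EffectiveRates(2.0, 5.0)).mbar is None

    def test_report_carries_origin_eigenvalue(self):
        rates = EffectiveRates(0.25, 2.0)
        below = mixing_threshold(rates, m=0.5)
        above = mixing_threshold(rates, m=0.7)
        assert not below.origin_stable and below.leading_eigenvalue > 0
        assert above.origin_stable and above.leading_eigenvalue < 0

    @given(st.floats(1.05, 5.0), st.floats(0.05, 0.95))
    def test_formula_agrees_with_eigenvalue_bisection(self, l2, prod):
        rates = EffectiveRates.from_pair(prod / l2, l2)
        mbar = mbar_formula(rates)
        assert 0.0 < mbar < 1.0
        assert abs(mbar - threshold_by_bisection(rates, tol=1e-10)) < 1e-6
        # sign structure around the threshold
        assert leading_origin_eigenvalue(rates, max(0.0, mbar - 1e-4)) > 0
        assert leading_origin_eigenvalue(rates, min(1.0, mbar + 1e-4)) < 0
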