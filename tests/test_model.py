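"""Core PSK population model: rates, closed forms, limits."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pskstab import (
    CopyNumber,
    Mechanism,
    PopulationState,
    PSKParams,
    asymptotic_fraction,
    closed_form_solution,
    copy_number_to_loss_prob,
    derivatives,
    fraction_at,
)
from conftest import random_params


def integrate_reference(state0, params, tau):
    """Independent oracle: adaptive high-order integration of the rate equations."""

    def rhs(_t, y):
        return derivatives(PopulationState(max(y[0], 0.0), max(y[1], 0.0)), params)

    sol = solve_ivp(
        rhs, (0.0, tau), [state0.x_plus, state0.x_minus],
        method="DOP853", rtol=1e-12, atol=1e-12,
    )
    return sol.y[0, -1], sol.y[1, -1]


class TestDerivatives:
    @pytest.mark.parametrize(
        "params, state, expected",
        [
            # perfect TA killing exactly cancels the loss influx
            (PSKParams(0.3, 1.2, 1.0, Mechanism.TA), PopulationState(1.0, 0.0),
             (1.2 * 0.7, 0.0)),
            # no loss: independent exponential growth
            (PSKParams(0.0, 0.8, 0.0, Mechanism.TA), PopulationState(2.0, 3.0),
             (1.6, 3.0)),
            # bacteriocin killing 2*omega*X- cancels X- growth at omega=1/2
            (PSKParams(0.1, 1.0, 0.5, Mechanism.BACTERIOCIN), PopulationState(1.0, 5.0),
             (0.9, 0.1)),
        ],
    )
    def test_printed_examples(self, params, state, expected):
        d = derivatives(state, params)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_none_mechanism_ignores_omega(self):
        p = PSKParams(0.1, 1.0, 0.9, Mechanism.NONE)
        assert p.omega == 0.0
        d = derivatives(PopulationState(1.0, 0.0), p)
        assert d[1] == pytest.approx(0.1)


class TestClosedForm:
    def test_matches_adaptive_integration(self, rng):
        for _ in range(100):
            params = random_params(rng)
            s0 = PopulationState(rng.uniform(0.1, 10), rng.uniform(0, 10))
            tau = rng.uniform(0, 8)
            got = closed_form_solution(s0, params, tau)
            ref = integrate_reference(s0, params, tau)
            assert got.x_plus == pytest.approx(ref[0], rel=1e-8)
            assert got.x_minus == pytest.approx(ref[1], rel=1e-8, abs=1e-10)

    def test_zero_time_is_identity(self, ta_params):
        s0 = PopulationState(2.0, 1.0)
        s = closed_form_solution(s0, ta_params, 0.0)
        assert (s.x_plus, s.x_minus) == (2.0, 1.0)

    def test_ta_loss_fraction(self):
        # lambda=0.1, gamma=1, no killing: fraction decays as exp(-lambda tau)
        p = PSKParams(0.1, 1.0, 0.0, Mechanism.TA)
        tau = math.log(1000)
        s = closed_form_solution(PopulationState(1.0, 0.0), p, tau)
        assert s.fraction == pytest.approx(math.exp(-0.1 * tau), rel=1e-10)
        assert s.fraction == pytest.approx(0.501, abs=5e-4)

    def test_bacteriocin_fraction(self):
        p = PSKParams(0.1, 1.0, 0.5, Mechanism.BACTERIOCIN)
        tau = math.log(1000)
        s = closed_form_solution(PopulationState(1.0, 0.0), p, tau)
        expected_minus = (0.1 / 0.9) * (math.exp(0.9 * tau) - 1.0)
        assert s.x_minus == pytest.approx(expected_minus, rel=1e-10)
        assert s.fraction == pytest.approx(0.900, abs=5e-4)

    def test_perfect_killing_keeps_population_pure(self):
        p = PSKParams(0.2, 0.9, 1.0, Mechanism.TA)
        for tau in [0.5, 3.0, 20.0]:
            s = closed_form_solution(PopulationState(1.0, 0.0), p, tau)
            assert s.x_minus == 0.0
            assert s.fraction == 1.0

    def test_non_negativity_random_grid(self, rng):
        for _ in range(200):
            params = random_params(rng)
            s0 = PopulationState(rng.uniform(0, 5), rng.uniform(0, 5))
            s = closed_form_solution(s0, params, rng.uniform(0, 10))
            assert s.x_plus >= 0 and s.x_minus >= 0

    def test_resonant_case_matches_integrator(self):
        # gamma*(1-lambda) == 1 exactly: resonant t*exp form
        lam = 0.2
        p = PSKParams(lam, 1.0 / (1.0 - lam), 0.0, Mechanism.TA)
        s0 = PopulationState(1.0, 0.5)
        got = closed_form_solution(s0, p, 2.0)
        ref = integrate_reference(s0, p, 2.0)
        assert got.x_plus == pytest.approx(ref[0], rel=1e-8)
        assert got.x_minus == pytest.approx(ref[1], rel=1e-8)

    def test_negative_tau_rejected(self, ta_params):
        with pytest.raises(ValueError):
            closed_form_solution(PopulationState(1.0, 0.0), ta_params, -1.0)


class TestFractionMonotonicity:
    def test_decreasing_in_lambda(self):
        tau = 10.0
        for mech in (Mechanism.TA, Mechanism.BACTERIOCIN):
            fracs = [
                fraction_at(PSKParams(lam, 0.9, 0.5, mech), tau)
                for lam in [1e-4, 1e-3, 1e-2, 0.1, 0.3]
            ]
            assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_increasing_in_omega(self):
        tau = 10.0
        for mech in (Mechanism.TA, Mechanism.BACTERIOCIN):
            fracs = [
                fraction_at(PSKParams(0.01, 0.9, om, mech), tau)
                for om in [0.0, 0.25, 0.5, 0.75, 1.0]
            ]
            assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestCopyNumber:
    def test_single_copy_always_lost(self):
        assert copy_number_to_loss_prob(CopyNumber(1.0)) == 1.0

    def test_low_copy_sc101(self):
        # n ~ 4.8 for the SC101 origin
        assert copy_number_to_loss_prob(CopyNumber(4.8)) == pytest.approx(
            2.0 ** (-3.8), rel=1e-12
        )

    def test_high_copy(self):
        assert copy_number_to_loss_prob(CopyNumber(21.0)) == pytest.approx(2.0**-20)

    def test_strictly_decreasing(self):
        ns = np.linspace(1, 30, 40)
        lams = [copy_number_to_loss_prob(float(n)) for n in ns]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_clip_below_one_copy(self):
        assert copy_number_to_loss_prob(0.5) == 1.0

    def test_invalid_copy_number(self):
        with pytest.raises(ValueError):
            copy_number_to_loss_prob(0.0)
        with pytest.raises(ValueError):
            CopyNumber(-2.0)


class TestAsymptoticFraction:
    def test_plasmid_free_outgrows(self):
        assert asymptotic_fraction(PSKParams(0.01, 0.9, 0.0, Mechanism.TA)) == 0.0

    def test_no_loss(self):
        assert asymptotic_fraction(PSKParams(0.0, 0.8, 0.0, Mechanism.TA)) == 1.0

    def test_bacteriocin_coexistence(self):
        p = PSKParams(0.1, 1.0, 0.5, Mechanism.BACTERIOCIN)
        assert asymptotic_fraction(p) == pytest.approx(0.9)

    def test_matches_long_time_closed_form(self):
        p = PSKParams(0.05, 1.0, 0.8, Mechanism.BACTERIOCIN)
        assert asymptotic_fraction(p) == pytest.approx(
            float(fraction_at(p, 200.0)), abs=1e-9
        )

    def test_exponent_tie_degenerate(self):
        lam = 0.1
        p = PSKParams(lam, 1.0 / (1.0 - lam), 0.0, Mechanism.TA)
        assert asymptotic_fraction(p) == 0.0


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lambda_loss=-0.1, gamma=1.0),
            dict(lambda_loss=1.5, gamma=1.0),
            dict(lambda_loss=0.1, gamma=0.0),
            dict(lambda_loss=0.1, gamma=1.0, omega=2.0),
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            PSKParams(**kwargs)

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            PopulationState(-1.0, 0.0)
        with pytest.raises(ValueError):
            PopulationState(0.0, 0.0).fraction
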