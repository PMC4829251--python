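import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from afprog import (
    PatientState,
    NEVER,
    age_activation,
    age_recovery,
    total_activation,
    total_recovery,
    evolve_sr,
    evolve_af,
    sr_cumulative_hazard,
    invert_sr_hazard,
    invert_af_hazard,
    apply_termination_boost,
    baseline_parameters,
)
from afprog.parameters import SECONDS_PER_YEAR

BASE = baseline_parameters()


def sr_state(t=0.0, Aepi=0.0, Repi=0.0):
    return PatientState(t=t, S=0, Aepi=Aepi, Repi=Repi)


def af_state(t=0.0, Aepi=0.0, Repi=0.0):
    return PatientState(t=t, S=1, Aepi=Aepi, Repi=Repi)


class TestClosedForms:
    def test_sigmoid_midpoint(self):
        assert age_activation(BASE.tc, BASE) == pytest.approx(1460.0)

    def test_sigmoid_plateau_and_floor(self):
        assert age_activation(1000.0, BASE) == pytest.approx(2920.0)
        assert age_activation(0.0, BASE) == pytest.approx(
            BASE.A1 / (1 + math.exp(70 / 3)), rel=1e-12)

    def test_sigmoid_strictly_increasing(self):
        ts = np.linspace(0, 100, 400)
        vals = [age_activation(t, BASE) for t in ts]
        assert np.all(np.diff(vals) > 0)

    def test_recovery_at_birth_and_threshold_age(self):
        assert age_recovery(0.0, BASE) == BASE.R0
        # with the threshold-derived decay constant the mean age-50
        # episode is exactly 864 s = 14.4 min
        from afprog import lambda_from_threshold
        p = replace(BASE, lam=lambda_from_threshold())
        rate_per_sec = age_recovery(50.0, p) / SECONDS_PER_YEAR
        assert 1 / rate_per_sec == pytest.approx(864.0, rel=1e-12)

    def test_recovery_baseline_age_50(self):
        assert age_recovery(50.0, BASE) == pytest.approx(
            BASE.R0 * 840.0 ** -1.2, rel=1e-12)

    def test_total_activation_components(self):
        # at birth the age term is ~2% of A0 and the sum is A0-dominated
        assert total_activation(sr_state(t=0.0), BASE) == pytest.approx(
            BASE.A0, rel=0.05)
        assert total_activation(sr_state(t=1000.0, Aepi=BASE.Amax), BASE) == \
            pytest.approx(BASE.A0 + BASE.A1 + BASE.Amax)
        assert total_activation(sr_state(t=70.0), BASE) == pytest.approx(
            BASE.A0 + 1460.0)

    def test_total_recovery(self):
        r50 = age_recovery(50.0, BASE)
        assert total_recovery(sr_state(t=50.0), BASE) == pytest.approx(r50)
        assert total_recovery(sr_state(t=50.0, Repi=-r50 / 2), BASE) == \
            pytest.approx(r50 / 2)
        with pytest.raises(ValueError):
            total_recovery(sr_state(t=50.0, Repi=-r50), BASE)


class TestEvolution:
    def test_identity_at_zero_tau(self):
        s = sr_state(t=40.0, Aepi=100.0, Repi=5.0)
        assert evolve_sr(s, 0.0, BASE) == s
        a = af_state(t=40.0, Aepi=100.0, Repi=5.0)
        assert evolve_af(a, 0.0, BASE) == a

    def test_sr_decays_to_baseline(self):
        s = evolve_sr(sr_state(t=40.0, Aepi=100.0, Repi=5.0), 50.0, BASE)
        assert s.Aepi == pytest.approx(0.0, abs=1e-12)
        assert s.Repi == pytest.approx(0.0, abs=1e-12)

    def test_af_fixed_point_at_amax(self):
        a = af_state(t=60.0, Aepi=BASE.Amax)
        for tau in (0.01, 0.5, 3.0):
            assert evolve_af(a, tau, BASE).Aepi == pytest.approx(BASE.Amax)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(t=st.floats(0, 90), aepi=st.floats(0, 5840),
           repi=st.floats(-100, 1000), tau=st.floats(1e-6, 0.5))
    def test_sr_matches_ode_integration(self, t, aepi, repi, tau):
        """Closed-form SR propagation equals adaptive integration of the
        linear relaxation ODEs to 1e-8 relative."""
        sol = solve_ivp(
            lambda _, y: [-BASE.beta * y[0], -BASE.nu * y[1]],
            (0, tau), [aepi, repi], rtol=1e-11, atol=1e-14)
        got = evolve_sr(sr_state(t, aepi, repi), tau, BASE)
        assert got.Aepi == pytest.approx(sol.y[0, -1], rel=1e-8, abs=1e-10)
        assert got.Repi == pytest.approx(sol.y[1, -1], rel=1e-8, abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(t=st.floats(0, 90), aepi=st.floats(0, 5840),
           repi=st.floats(0, 1000), tau=st.floats(1e-6, 0.05))
    def test_af_matches_ode_integration(self, t, aepi, repi, tau):
        """Closed-form AF propagation (saturating activation; total
        recovery decaying at rate mu, episode part by subtraction)
        equals adaptive ODE integration to 1e-8 relative."""
        r0_total = age_recovery(t, BASE) + repi
        sol = solve_ivp(
            lambda _, y: [BASE.alpha * (BASE.Amax - y[0]), -BASE.mu * y[1]],
            (0, tau), [aepi, r0_total], rtol=1e-11, atol=1e-14)
        got = evolve_af(af_state(t, aepi, repi), tau, BASE)
        assert got.Aepi == pytest.approx(sol.y[0, -1], rel=1e-8, abs=1e-10)
        want_repi = sol.y[1, -1] - age_recovery(t + tau, BASE)
        assert got.Repi == pytest.approx(want_repi, rel=1e-8, abs=1e-8)


class TestSRHazard:
    def test_zero_tau(self):
        assert sr_cumulative_hazard(sr_state(t=50.0), 0.0, BASE) == 0.0

    def test_homogeneous_limit(self):
        p = replace(BASE, A1=0.0)
        s = sr_state(t=10.0)
        assert sr_cumulative_hazard(s, 3.0, p) == pytest.approx(p.A0 * 3.0)

    @pytest.mark.parametrize("t,aepi,tau", [
        (0.0, 0.0, 1.0), (50.0, 0.0, 1.0), (69.0, 500.0, 2.0),
        (75.0, 5840.0, 0.3), (95.0, 10.0, 4.9),
    ])
    def test_matches_quadrature(self, t, aepi, tau):
        """The softplus antiderivative equals adaptive quadrature of the
        instantaneous activation rate to 1e-9 relative."""
        want, err = quad(
            lambda s: BASE.A0 + age_activation(t + s, BASE)
            + aepi * math.exp(-BASE.beta * s),
            0, tau, epsabs=1e-13, epsrel=1e-12, limit=200)
        got = sr_cumulative_hazard(sr_state(t, aepi), tau, BASE)
        assert got == pytest.approx(want, rel=1e-9, abs=max(1e-9, 10 * err))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t=st.floats(0, 95), aepi=st.floats(0, 5840),
           tau1=st.floats(1e-4, 2), tau2=st.floats(1e-4, 2))
    def test_strictly_increasing(self, t, aepi, tau1, tau2):
        lo, hi = sorted((tau1, tau2))
        if hi - lo < 1e-9:
            return
        s = sr_state(t, aepi)
        assert sr_cumulative_hazard(s, hi, BASE) > \
            sr_cumulative_hazard(s, lo, BASE)


class TestSRInversion:
    def test_constant_rate_closed_form(self):
        p = replace(BASE, A1=0.0, A0=2.5)
        assert invert_sr_hazard(sr_state(t=5.0), 1.0, p) == \
            pytest.approx(1.0 / 2.5, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t=st.floats(0, 95), aepi=st.floats(0, 5840),
           tau0=st.floats(1e-6, 3))
    def test_round_trip(self, t, aepi, tau0):
        s = sr_state(t, aepi)
        E = sr_cumulative_hazard(s, tau0, BASE)
        if E <= 0:
            return
        tau = invert_sr_hazard(s, E, BASE)
        assert sr_cumulative_hazard(s, tau, BASE) == pytest.approx(
            E, abs=1e-9 * max(1.0, E))

    def test_residual_against_quadrature(self):
        s = sr_state(t=65.0, Aepi=300.0)
        E = 2.5
        tau = invert_sr_hazard(s, E, BASE)
        want, _ = quad(
            lambda u: BASE.A0 + age_activation(65.0 + u, BASE)
            + 300.0 * math.exp(-BASE.beta * u),
            0, tau, epsabs=1e-13, epsrel=1e-12, limit=200)
        assert want == pytest.approx(E, abs=1e-8)


class TestAFInversion:
    def test_homogeneous_limit(self):
        p = replace(BASE, mu=0.0)
        s = af_state(t=50.0)
        r = age_recovery(50.0, BASE)
        assert invert_af_hazard(s, 1.7, p) == pytest.approx(1.7 / r, rel=1e-12)

    def test_hazard_bound_gives_never(self):
        s = af_state(t=90.0, Repi=0.0)
        r = age_recovery(90.0, BASE)
        assert invert_af_hazard(s, r / BASE.mu, BASE) is NEVER
        assert invert_af_hazard(s, 2 * r / BASE.mu, BASE) is NEVER

    def test_closed_form_example(self):
        # R_enter = 100/yr, mu = 52/yr, E = 1  ->  tau = -ln(1 - 0.52)/52
        p = replace(BASE, mu=52.0)
        t = math.log(p.R0 / 100.0) / p.lam  # age where Rage = 100
        s = af_state(t=t, Repi=0.0)
        tau = invert_af_hazard(s, 1.0, p)
        assert tau == pytest.approx(-math.log(1 - 0.52) / 52.0, rel=1e-9)
        # independent cross-check: quadrature + root finding
        oracle = brentq(
            lambda x: quad(lambda u: 100.0 * math.exp(-52.0 * u), 0, x)[0] - 1.0,
            1e-12, 1.0, xtol=1e-15)
        assert tau == pytest.approx(oracle, rel=1e-7)

    def test_requires_positive_recovery(self):
        s = af_state(t=50.0, Repi=-2 * age_recovery(50.0, BASE))
        with pytest.raises(ValueError):
            invert_af_hazard(s, 1.0, BASE)


class TestTerminationBoost:
    def test_sign_flip(self):
        out = apply_termination_boost(af_state(t=60.0, Repi=-0.5), BASE)
        assert out.Repi == 0.5 and out.S == 0

    def test_no_boost_branch(self):
        out = apply_termination_boost(af_state(t=60.0, Repi=0.2), BASE)
        assert out.Repi == 0.2

    def test_zero_boost_factor(self):
        p = replace(BASE, B=0.0)
        out = apply_termination_boost(af_state(t=60.0, Repi=-0.5), p)
        assert out.Repi == 0.0

    def test_activation_continuous_across_transition(self):
        out = apply_termination_boost(af_state(t=60.0, Aepi=1234.5,
                                               Repi=-1.0), BASE)
        assert out.Aepi == 1234.5


@settings(max_examples=60, deadline=None, derandomize=True)
@given(steps=st.lists(
    st.tuples(st.sampled_from(["sr", "af"]), st.floats(0, 0.2)),
    min_size=1, max_size=12),
    aepi0=st.floats(0, 5840))
def test_aepi_stays_in_range(steps, aepi0):
    """Aepi never leaves [0, Amax] under any evolve/boost sequence."""
    s = sr_state(t=0.0, Aepi=aepi0)
    for phase, tau in steps:
        if s.t + tau > 99.0:
            break
        if phase == "sr":
            s = evolve_sr(replace(s, S=0), tau, BASE)
        else:
            s = evolve_af(replace(s, S=1), tau, BASE)
            s = apply_termination_boost(s, BASE)
        assert 0.0 <= s.Aepi <= BASE.Amax
        # boosted recovery component keeps the total rate positive
        assert age_recovery(s.t, BASE) + s.Repi > 0.0
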