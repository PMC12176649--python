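"""Core tube mechanics: Laplace law, tension decomposition, steady states,
elastic pressure jumps and the constrained ODE integrator."""
import numpy as np
import pytest
from scipy.optimize import brentq

import nematube as nt
from nematube.tube import _rhs_factory


class TestLaplaceTension:
    @pytest.mark.parametrize("dP,R,expected", [
        (650.0, 100e-6, 0.065),
        (0.0, 80e-6, 0.0),
        (150.0, 62.5e-6, 9.375e-3),
    ])
    def test_values(self, dP, R, expected):
        assert nt.laplace_tension(dP, R) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            nt.laplace_tension(650.0, 0.0)


class TestActinTension:
    def test_isotropic_split(self, params):
        tc, tl = nt.actin_tension(0.0, 0.0, params)
        assert tc == pytest.approx(params.zeta0 / 2)
        assert tl == pytest.approx(params.zeta0 / 2)

    def test_fully_circumferential(self, params):
        tc, tl = nt.actin_tension(0.0, 0.5, params)
        assert tc == pytest.approx(params.zeta0)
        assert tl == 0.0

    def test_closed_form_and_additivity(self, params):
        p = params.replace(zeta0=0.0234, Ka=0.22)
        s, q = 0.2, -0.1
        tc, tl = nt.actin_tension(s, q, p)
        mag = 0.0234 + 0.22 * 0.2
        assert tc == pytest.approx(mag * 0.4, rel=1e-14)
        assert tl == pytest.approx(mag * 0.6, rel=1e-14)
        assert tc + tl == pytest.approx(mag, rel=1e-14)

    def test_compressive_warns(self, params):
        p = params.replace(zeta0=0.01, Ka=0.22)
        with pytest.warns(RuntimeWarning, match="compressive"):
            nt.actin_tension(-0.2, 0.0, p)


class TestScalarRhs:
    def test_nematic_fixed_points(self, params):
        assert nt.nematic_rhs(params.q0, 0.0, 0.0, params) == 0.0
        assert nt.nematic_rhs(-params.q0, 0.0, 0.0, params) == 0.0
        assert nt.nematic_rhs(0.0, 0.0, 0.0, params) == 0.0

    def test_circumferential_tension_drives_q_up(self, params):
        # residual tension anisotropy tilts the potential
        val = nt.nematic_rhs(-params.q0, 1e-3, 0.0, params)
        assert val == pytest.approx(params.beta * 5e-4)
        assert val > 0

    def test_maxwell_relaxed_state_stationary(self, params):
        assert nt.residual_rhs(0.0, 0.0, params) == 0.0

    def test_maxwell_steady_creep_and_elastic_limits(self, params):
        v = 0.02
        # creep fixed point tr = mu*v
        assert nt.residual_rhs(params.mu * v, v, params) == pytest.approx(0.0)
        # short-time elastic modulus: d(tr)/d(eps) = mu/tau = K
        assert nt.residual_rhs(0.0, v, params) / v == pytest.approx(params.K)

    @pytest.mark.parametrize("q,v,expected", [
        (0.5, 0.03, 0.03),
        (-0.5, 0.03, 0.0),
        (0.0, 0.03, 0.015),
    ])
    def test_strain_projection(self, q, v, expected):
        assert nt.strain_rhs(q, v) == pytest.approx(expected)


class TestInitialSteadyState:
    def test_zeta0_closure_value(self):
        p = nt.ModelParams(q0=0.1)
        st = nt.initial_steady_state(150.0, p)
        p2 = p.with_zeta0_closure(150.0)
        assert p2.zeta0 == pytest.approx(9.375e-3 / 0.4, rel=1e-12)
        assert st.q == -0.1 and st.s == 0.0
        assert st.tr_c == 0.0 and st.tr_l == 0.0 and st.R == p.R0

    def test_isotropic_limit(self):
        p = nt.ModelParams(q0=1e-9)
        z = p.with_zeta0_closure(150.0).zeta0
        assert z == pytest.approx(2 * 150.0 * p.R0, rel=1e-6)

    def test_nematic_fixed_point_property(self, params):
        st = nt.initial_steady_state(150.0, params)
        assert nt.nematic_rhs(st.q, st.tr_c, st.tr_l, params) == 0.0

    def test_inconsistent_zeta0_rejected(self):
        p = nt.ModelParams(zeta0=0.5)
        with pytest.raises(nt.ParameterError, match="inconsistent"):
            nt.initial_steady_state(150.0, p)


class TestPressureJump:
    def test_noop(self, params):
        st = nt.initial_steady_state(150.0, params)
        st2 = nt.pressure_jump(st, 150.0, params)
        assert st2.R == st.R and st2.s == st.s

    def test_against_bisection_oracle(self):
        # frozen scenario: 150 -> 650 Pa at q=-0.1 with K = 0.31 N/m
        p = nt.ModelParams(q0=0.1, Ka=0.22, mu=0.31, tau=1.0)
        p = p.with_zeta0_closure(150.0)
        st = nt.initial_steady_state(150.0, p)
        st2 = nt.pressure_jump(st, 650.0, p)

        def f(x):
            s2 = (0.5 + st.q) * x
            return (650.0 * st.R * np.exp(x)
                    - (p.zeta0 + p.Ka * s2) * (0.5 + st.q) - p.K * x)

        # independent bisection
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        x_oracle = 0.5 * (lo + hi)
        assert np.log(st2.R / st.R) == pytest.approx(x_oracle, abs=1e-10)
        assert st2.R / st.R == pytest.approx(np.exp(x_oracle), rel=1e-8)
        assert 1.05 < st2.R / st.R < 1.2  # order 1.1 expansion

    def test_laplace_satisfied_after_jump(self, params):
        st = nt.initial_steady_state(150.0, params)
        st2 = nt.pressure_jump(st, 850.0, params)
        tc, _ = st2.tensions(params)
        assert abs(850.0 * st2.R - tc) <= 1e-10 * 850.0 * st2.R

    def test_rigid_limit(self, params):
        st = nt.initial_steady_state(150.0, params)
        p_stiff = params.replace(Ka=1e4)
        st2 = nt.pressure_jump(st, 650.0, p_stiff)
        assert np.log(st2.R / st.R) < 1e-3
        p_stiff2 = params.replace(mu=1e4)  # K = mu/tau large
        st3 = nt.pressure_jump(st, 650.0, p_stiff2)
        assert np.log(st3.R / st.R) < 1e-3


class TestIntegrateTube:
    def test_constant_pressure_preserves_steady_state(self, params):
        proto = nt.PressureProtocol(segments=((0.0, 150.0),))
        traj = nt.integrate_tube(proto, params, np.linspace(0, 56, 57))
        assert np.allclose(traj.R, params.R0, rtol=1e-4)
        assert np.allclose(traj.q, -params.q0, atol=1e-4 * params.q0)
        assert np.allclose(traj.tr_c, 0.0, atol=1e-4 * params.zeta0)

    def test_laplace_invariant(self, default_traj):
        assert default_traj.laplace_residual().max() <= 1e-6

    def test_tension_additivity(self, default_traj):
        t_c = default_traj.t_a_c + default_traj.tr_c
        t_l = default_traj.t_a_l + default_traj.tr_l
        assert np.allclose(t_c, default_traj.t_c, rtol=1e-12)
        assert np.allclose(t_l, default_traj.t_l, rtol=1e-12)

    def test_longitudinal_residual_stays_zero(self, default_traj):
        assert np.allclose(default_traj.tr_l, 0.0, atol=1e-15)

    def test_jump_matches_fast_ramp(self, params):
        # instantaneous elastic jump == limit of a very fast ramp
        proto_fast = nt.PressureProtocol(
            segments=((-1.0, 150.0), (0.0, 650.0)), ramp_duration=1e-3)
        traj = nt.integrate_tube(proto_fast, params, np.array([2e-3, 1.0]))
        st = nt.initial_steady_state(150.0, params)
        st_jump = nt.pressure_jump(st, 650.0, params)
        assert traj.R[0] == pytest.approx(st_jump.R, rel=1e-3)

    def test_beta_zero_q_never_flips(self, params, grid):
        # without the tension coupling the fibres never reorient; the tube
        # creeps without the nematic brake until elastic capacity runs out
        p = params.replace(beta=0.0)
        traj = nt.integrate_tube(nt.step_protocol(), p, grid,
                                 on_instability="truncate")
        assert np.all(traj.q < 0)
        assert traj.R[-1] > 1.5 * params.R0  # unbraked creep

    def test_Ka_zero_runaway_no_plateau(self, params, grid):
        p = params.replace(Ka=1e-12)
        traj = nt.integrate_tube(nt.step_protocol(), p, grid,
                                 on_instability="truncate")
        assert traj.terminated_early
        # expansion accelerates toward the runaway; no plateau forms
        assert traj.growth_rate(traj.t[-1]) > 1e-2

    def test_monotone_in_pressure_at_7h(self, params):
        R7, q7 = [], []
        for dP in nt.PRESSURE_LEVELS:
            proto = nt.step_protocol(dP_high=dP)
            traj = nt.integrate_tube(proto, params, np.array([0.0, 7.0]))
            R7.append(traj.R[-1])
            q7.append(traj.q[-1])
        assert np.all(np.diff(R7) >= 0)
        assert np.all(np.diff(q7) >= 0)

    def test_instability_raises_by_default(self, params, grid):
        p = params.replace(Ka=1e-12)
        with pytest.raises(nt.LaplaceInstabilityError):
            nt.integrate_tube(nt.step_protocol(), p, grid)

    def test_bad_grid_rejected(self, params):
        with pytest.raises(ValueError):
            nt.integrate_tube(nt.step_protocol(), params, np.array([5.0, 1.0]))


class TestOracleEquivalence:
    """The eliminated-dR/dt integrator against an independent stepping
    scheme that solves the algebraic Laplace constraint at every step."""

    @staticmethod
    def _oracle(p, proto, t_end, dt):
        t = proto.t_start
        q, s, trc, trl, R = -p.q0, 0.0, 0.0, 0.0, p.R0
        ts, Rs, qs = [t], [R], [q]
        while t < t_end - 1e-12:
            h = min(dt, t_end - t)
            t2 = t + h
            dP2 = proto.pressure(t2)
            qdot = -p.gamma * (q * q - p.q0 ** 2) * q + p.beta * 0.5 * (trc - trl)
            q2 = q + h * qdot
            qm = 0.5 * (q + q2)

            def f(x):
                s2 = s + (0.5 + qm) * x
                trc2 = trc + (p.mu * x - trc * h) / p.tau
                return (dP2 * R * np.exp(x)
                        - ((p.zeta0 + p.Ka * s2) * (0.5 + q2) + trc2))

            x = brentq(f, -0.5, 0.5, xtol=1e-15)
            s += (0.5 + qm) * x
            trc += (p.mu * x - trc * h) / p.tau
            trl += -trl * h / p.tau
            q, R, t = q2, R * np.exp(x), t2
            ts.append(t), Rs.append(R), qs.append(q)
        return np.array(ts), np.array(Rs), np.array(qs)

    def test_default_scenario(self, params, default_traj):
        ts, Rs, qs = self._oracle(params, nt.step_protocol(), 56.0, 0.002)
        Ro = np.interp(default_traj.t, ts, Rs)
        qo = np.interp(default_traj.t, ts, qs)
        assert np.max(np.abs(Ro - default_traj.R) / default_traj.R) < 1e-4
        assert np.max(np.abs(qo - default_traj.q)) < 5e-4
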