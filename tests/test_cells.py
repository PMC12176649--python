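"""Cell-scale observables: area shear decomposition, elongation dynamics,
division-rate inference."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

import nematube as nt
from nematube.cells import InferenceError


class TestAreaTrajectory:
    def test_static_no_division(self):
        t = np.linspace(0, 48, 20)
        a = nt.area_trajectory(t, np.full_like(t, 60e-6), kd=0.0)
        assert np.allclose(a, 1.0)

    def test_pure_dilation(self):
        t = np.array([0.0, 10.0])
        a = nt.area_trajectory(t, np.array([60e-6, 120e-6]), kd=0.0)
        assert a[-1] == pytest.approx(2.0)

    def test_division_decay_closed_form(self):
        t = np.array([0.0, 24.0])
        a = nt.area_trajectory(t, np.array([60e-6, 60e-6]), kd=0.27)
        assert a[-1] == pytest.approx(np.exp(-0.27), rel=1e-12)

    def test_matches_ode_quadrature_on_model_trajectory(self, default_traj,
                                                        params):
        # closed form vs direct integration of (1/a) da/dt = dlnR/dt - kd
        tt = np.linspace(0.0, 56.0, 3001)
        lnR = default_traj.states_at(tt)[0]
        dlnR = CubicSpline(tt, lnR).derivative()
        kd_h = params.kd / 24.0
        sol = solve_ivp(lambda t, y: [dlnR(t) - kd_h], (0, 56), [0.0],
                        t_eval=default_traj.t, rtol=1e-12, atol=1e-12)
        a_ode = np.exp(sol.y[0])
        a_closed = nt.area_trajectory(default_traj.t, default_traj.R,
                                      params.kd)
        assert np.allclose(a_closed, a_ode, rtol=1e-8)

    def test_transient_peak_then_decline(self, default_traj):
        a = default_traj.a_rel
        assert a.max() > 1.0
        assert a[-1] < a.max()


class TestElongationTrajectory:
    def test_pure_advection_limit(self, default_traj, params):
        # lam = 0: dQ = (1/2) ln(R+/R-)
        t, Q = nt.elongation_trajectory(default_traj, params, lam=0.0)
        expected = Q[0] + nt.shear_deltaQ(default_traj.R[0], default_traj.R)
        assert np.allclose(Q, expected, atol=1e-9)

    def test_slaved_limit(self, default_traj, params):
        lam = 200.0
        t, Q = nt.elongation_trajectory(default_traj, params, lam=lam)
        # fast relaxation slaves Q to alpha*q up to the adiabatic correction
        # (v/2 - alpha dq/dt)/lam
        late = t > 1.0
        v = np.gradient(np.log(default_traj.R), t)
        qdot = np.gradient(default_traj.q, t)
        bound = (np.abs(v) / 2 + params.alpha * np.abs(qdot)) / lam
        gap = np.abs(Q - params.alpha * default_traj.q)
        assert np.all(gap[late] <= 2 * bound[late] + 2e-4)

    def test_Q_crosses_zero_after_q(self, default_traj, params):
        t, Q = nt.elongation_trajectory(default_traj, params)
        tq = default_traj.t[np.argmax(default_traj.q > 0)]
        tQ = t[np.argmax(Q > 0)]
        assert tQ >= tq

    def test_consistent_with_integrated_state(self, default_traj, params):
        # the trajectory carries Q integrated jointly with the tube ODEs
        t, Q = nt.elongation_trajectory(default_traj, params)
        assert np.allclose(Q, default_traj.Q, atol=2e-4)


class TestInferKd:
    def test_exact_on_noiseless_input(self):
        t = np.array([0.0, 7.0, 24.0, 56.0])
        R = 62.5e-6 * np.exp(0.002 * t)
        a = nt.area_trajectory(t, R, kd=0.27)
        kd, se = nt.infer_kd_from_area(t, a, R)
        assert kd == pytest.approx(0.27, rel=1e-10)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_constant_series_gives_zero(self):
        t = np.array([0.0, 7.0, 24.0, 56.0])
        R = np.full(4, 60e-6)
        kd, _ = nt.infer_kd_from_area(t, np.ones(4), R)
        assert kd == pytest.approx(0.0, abs=1e-14)

    def test_too_few_points_rejected(self):
        with pytest.raises(InferenceError):
            nt.infer_kd_from_area(np.array([0.0, 1.0]), np.ones(2),
                                  np.full(2, 60e-6))

    def test_noisy_recovery_within_2se(self):
        rng = np.random.default_rng(7)
        t = np.array([0.0, 7.0, 24.0, 56.0])
        R = np.full(4, 62.5e-6)
        a_true = nt.area_trajectory(t, R, kd=0.27)
        reps = a_true[None, :] + rng.normal(0, 0.05, size=(8, 4))
        kd, se = nt.infer_kd_from_area(t, reps, R)
        assert abs(kd - 0.27) <= 2 * se


class TestEduRate:
    def test_zero_positive_fraction(self):
        assert nt.edu_to_rate(0, 500, 8.0) == 0.0

    def test_inverse_round_trip(self):
        f = 1.0 - np.exp(-0.27 * 8.0 / 24.0)
        n = 10 ** 6
        kd = nt.edu_to_rate(int(round(f * n)), n, 8.0)
        assert kd == pytest.approx(0.27, rel=1e-4)

    def test_linear_convention(self):
        assert nt.edu_to_rate(10, 1000, 8.0, convention="linear") == \
            pytest.approx(0.01 / (8 / 24))

    def test_saturated_rejected(self):
        with pytest.raises(ValueError, match="unbounded"):
            nt.edu_to_rate(100, 100, 8.0)

    def test_monte_carlo_estimator_centred(self):
        # binomial counts at true kd: estimator distribution centred on truth
        counts = nt.generate_edu(0.27, 8.0, 2000, seed=11, n_replicates=1000)
        ests = np.array([nt.edu_to_rate(npos, ntot, 8.0)
                         for npos, ntot in counts])
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.27) < 4 * se + 1e-3


class TestDensityDependence:
    def test_round_trip_exact(self):
        rho = np.array([500.0, 1000.0, 1500.0, 2500.0, 4000.0])
        kd = 0.8 * np.exp(-rho / 1200.0)
        kmax, rc, resid = nt.fit_density_dependence(rho, kd)
        assert kmax == pytest.approx(0.8, rel=1e-6)
        assert rc == pytest.approx(1200.0, rel=1e-6)
        assert resid < 1e-12

    def test_constant_rates_degenerate(self):
        rho = np.array([500.0, 1000.0, 2000.0, 3000.0])
        kmax, rc, _ = nt.fit_density_dependence(rho, np.full(4, 0.3))
        assert np.isinf(rc)
        assert kmax == pytest.approx(0.3)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(3)
        rho = np.linspace(400, 4000, 12)
        kd = 0.8 * np.exp(-rho / 1200.0) + rng.normal(0, 0.02, 12)
        kmax, rc, _ = nt.fit_density_dependence(rho, np.clip(kd, 0, None))
        assert kmax == pytest.approx(0.8, rel=0.25)
        assert rc == pytest.approx(1200.0, rel=0.35)

    def test_too_few_rows(self):
        with pytest.raises(InferenceError):
            nt.fit_density_dependence(np.array([1.0, 2.0, 3.0]),
                                      np.array([0.1, 0.2, 0.3]))
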