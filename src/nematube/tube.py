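"""Axisymmetric dynamics of a pressurized endothelial tube.

The tube is a thin active surface wrapped on a cylinder of radius ``R``.
On this geometry every tensor of the model is diagonal in the
(circumferential, longitudinal) basis and is stored through its mixed
components; the co-rotational time derivative then reduces to a plain time
derivative.  The scalar state is

* ``R``   — tube radius (m),
* ``q``   — circumferential nematic order of the actin fibres
  (``q = q_theta^theta = -q_z^z``),
* ``s``   — elongational strain accumulated along the fibres,
* ``tr_c``, ``tr_l`` — circumferential / longitudinal residual (Maxwell)
  tension (N/m).

The total tension is ``t = t_a + t_r`` with the actin part
``t_a = (zeta0 + Ka*s) * n`` acting along the mean fibre orientation
``n = g/2 + q`` and the residual part obeying a Maxwell law
``(1 + tau d/dt) t_r = mu v``.  Laplace's law ``dP * R = t_theta^theta``
closes the system; differentiating it in time eliminates ``dR/dt``.

The tube length is fixed by the channel, so the longitudinal strain rate
vanishes and ``tr_l`` stays at zero once relaxed; it is carried in the
state for model variants.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import ModelParams, PressureProtocol, ParameterError

__all__ = [
    "TubeState", "Trajectory", "LaplaceInstabilityError", "IntegrationError",
    "laplace_tension", "actin_tension", "nematic_rhs", "residual_rhs",
    "strain_rhs", "initial_steady_state", "pressure_jump", "integrate_tube",
]

HOURS_PER_DAY = 24.0


class LaplaceInstabilityError(RuntimeError):
    """Elastic capacity of the tube fell below the applied pressure load."""

    def __init__(self, message, trajectory=None, t_fail=None):
        super().__init__(message)
        self.trajectory = trajectory
        self.t_fail = t_fail


class IntegrationError(RuntimeError):
    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


def laplace_tension(dP: float, R: float) -> float:
    """Circumferential tension balancing pressure ``dP`` at radius ``R``.

    Laplace's law for a thin-walled cylinder: ``t = dP * R`` (N/m).
    """
    if np.any(np.asarray(R) <= 0):
        raise ValueError("radius must be strictly positive")
    if np.any(np.asarray(dP) < 0):
        raise ValueError("pressure must be non-negative")
    return dP * R


def actin_tension(s, q, p: ModelParams):
    """Circumferential and longitudinal tension of the actin fibre network.

    ``t_a = (zeta0 + Ka*s) * n`` with mixed orientation components
    ``n_c = 1/2 + q`` and ``n_l = 1/2 - q``; the two components always sum
    to the isotropic magnitude ``zeta0 + Ka*s``.
    """
    if p.zeta0 is None:
        raise ParameterError("zeta0 is unset; close it with with_zeta0_closure")
    mag = p.zeta0 + p.Ka * np.asarray(s)
    if np.any(mag < 0):
        warnings.warn("compressive fibre tension: zeta0 + Ka*s < 0",
                      RuntimeWarning, stacklevel=2)
    q = np.asarray(q)
    return mag * (0.5 + q), mag * (0.5 - q)


def nematic_rhs(q, tr_c, tr_l, p: ModelParams):
    """dq/dt: Landau relaxation toward magnitude ``q0`` plus the
    mechanosensitive drive by the traceless residual tension."""
    tr_tilde = 0.5 * (np.asarray(tr_c) - np.asarray(tr_l))
    return -p.gamma * (np.asarray(q) ** 2 - p.q0 ** 2) * q + p.beta * tr_tilde


def residual_rhs(tr, v, p: ModelParams):
    """Maxwell element: d(tr)/dt = (mu*v - tr)/tau, componentwise."""
    return (p.mu * np.asarray(v) - np.asarray(tr)) / p.tau


def strain_rhs(q, Rdot_over_R):
    """Fibre elongational strain rate ``v_kl n^kl = (Rdot/R)(1/2 + q)``
    (the longitudinal strain rate vanishes on the fixed-length tube)."""
    return np.asarray(Rdot_over_R) * (0.5 + np.asarray(q))


@dataclass
class TubeState:
    """Instantaneous state of the tube."""

    t: float
    R: float
    q: float
    s: float
    tr_c: float
    tr_l: float
    Q: float = 0.0
    a_rel: float = 1.0

    def __post_init__(self):
        if self.R <= 0:
            raise ParameterError("R must be positive")
        if abs(self.q) > 0.5 + 1e-12:
            raise ParameterError("|q| cannot exceed 1/2")

    def tensions(self, p: ModelParams):
        """(t_c, t_l) total tensions = actin + residual (N/m)."""
        ta_c, ta_l = actin_tension(self.s, self.q, p)
        return ta_c + self.tr_c, ta_l + self.tr_l


def initial_steady_state(dP0: float, p: ModelParams) -> TubeState:
    """Steady state of the cultured tube at pressure ``dP0``.

    The fibres sit on the longitudinal branch of the Landau potential
    (q = -q0), the elongational strain is referenced to this configuration
    (s = 0) and the Maxwell tension has relaxed.  ``zeta0`` is fixed by (or
    verified against) the Laplace balance ``zeta0 (1/2 - q0) = dP0 R0``.
    """
    if dP0 <= 0:
        raise ParameterError("dP0 must be positive")
    p = p.with_zeta0_closure(dP0)
    return TubeState(t=0.0, R=p.R0, q=-p.q0, s=0.0, tr_c=0.0, tr_l=0.0,
                     Q=-p.alpha * p.q0, a_rel=1.0)


def pressure_jump(state: TubeState, dP_new: float, p: ModelParams) -> TubeState:
    """Instantaneous elastic response to a pressure step.

    On timescales much shorter than ``tau`` and ``1/gamma`` the Maxwell
    element is a spring of modulus ``K = mu/tau`` and the nematic order is
    frozen, so the new radius solves the scalar balance (x = ln(R1/R))::

        dP_new * R * e^x = (zeta0 + Ka*(s + (1/2+q)*x)) * (1/2+q)
                           + tr_c + K*x

    by bracketed root finding.  Strain, residual tension, cell elongation
    and area are advected accordingly.
    """
    if p.zeta0 is None:
        raise ParameterError("zeta0 is unset; close it with with_zeta0_closure")
    q, s, trc = state.q, state.s, state.tr_c
    nc = 0.5 + q
    K = p.K

    def f(x):
        return (dP_new * state.R * np.exp(x)
                - (p.zeta0 + p.Ka * (s + nc * x)) * nc - trc - K * x)

    if abs(f(0.0)) <= 1e-14 * max(dP_new * state.R, p.zeta0):
        return state  # no-op jump

    xs = np.linspace(-5.0, 5.0, 4001)
    fs = f(xs)
    roots = []
    for i in np.nonzero(np.diff(np.sign(fs)) != 0)[0]:
        r = brentq(f, xs[i], xs[i + 1], xtol=1e-14, rtol=1e-14)
        roots.append(r)
    # keep mechanically stable roots: tension stiffens faster than the
    # Laplace load there (f' < 0)
    stable = [r for r in roots
              if (p.Ka * nc ** 2 + K) - dP_new * state.R * np.exp(r) > 0]
    if not stable:
        raise LaplaceInstabilityError(
            "elastic instability: tube expansion unbounded at this pressure")
    x = min(stable, key=abs)
    R1 = state.R * np.exp(x)
    new = TubeState(
        t=state.t, R=R1, q=q, s=s + nc * x, tr_c=trc + K * x,
        tr_l=state.tr_l, Q=state.Q + 0.5 * x, a_rel=state.a_rel * np.exp(x),
    )
    resid = abs(dP_new * new.R - new.tensions(p)[0])
    if resid > 1e-10 * max(dP_new * new.R, p.zeta0):
        raise IntegrationError("pressure jump failed to satisfy Laplace balance")
    return new


@dataclass
class Trajectory:
    """Time-indexed tube states plus derived observables.

    ``a_rel`` is the mean cell area normalized to its value at the first
    output time (the start of observations), the reference the measurements
    use.
    """

    t: np.ndarray
    R: np.ndarray
    q: np.ndarray
    s: np.ndarray
    tr_c: np.ndarray
    tr_l: np.ndarray
    Q: np.ndarray
    a_rel: np.ndarray
    params: ModelParams
    protocol: PressureProtocol
    terminated_early: bool = False
    termination_reason: Optional[str] = None
    _pieces: list = field(default_factory=list, repr=False)  # (t_lo, t_hi, dense)
    _jumps: list = field(default_factory=list, repr=False)   # (t, state_after)

    @property
    def dP(self) -> np.ndarray:
        return np.array([self.protocol.pressure(ti) for ti in self.t])

    @property
    def t_a_c(self) -> np.ndarray:
        return actin_tension(self.s, self.q, self.params)[0]

    @property
    def t_a_l(self) -> np.ndarray:
        return actin_tension(self.s, self.q, self.params)[1]

    @property
    def t_c(self) -> np.ndarray:
        """Total circumferential tension (N/m)."""
        return self.t_a_c + self.tr_c

    @property
    def t_l(self) -> np.ndarray:
        return self.t_a_l + self.tr_l

    def laplace_residual(self) -> np.ndarray:
        """|dP*R - t_c| / max(dP*R, zeta0) at every output time."""
        load = self.dP * self.R
        scale = np.maximum(load, self.params.zeta0)
        return np.abs(load - self.t_c) / scale

    def states_at(self, t) -> np.ndarray:
        """Dense state evaluation, shape (7, len(t)); left-continuous at
        instantaneous jumps.  Rows: lnR/R0, q, s, tr_c, tr_l, Q, ln a."""
        t = np.atleast_1d(np.asarray(t, float))
        out = np.empty((7, t.size))
        for j, tj in enumerate(t):
            for (lo, hi, dense) in self._pieces:
                if lo <= tj <= hi and dense is not None:
                    out[:, j] = dense(tj)
                    break
            else:
                raise ValueError(f"time {tj} outside integrated span")
        return out

    def growth_rate(self, t, dt: float = 0.25) -> float:
        """Relative expansion rate d(ln R)/dt at time ``t`` (h^-1)."""
        t = float(t)
        lo = max(t - dt, self._pieces[0][0])
        x = self.states_at([lo, t])[0]
        return (x[1] - x[0]) / (t - lo)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t_h": self.t, "R_m": self.R, "q": self.q, "s": self.s,
            "tr_c_Nm": self.tr_c, "tr_l_Nm": self.tr_l,
            "t_theta_Nm": self.t_c, "t_z_Nm": self.t_l,
            "Q": self.Q, "a_rel": self.a_rel,
        })


class _RhsBudgetExceeded(Exception):
    pass


def _rhs_factory(p: ModelParams, protocol: PressureProtocol,
                 max_calls: Optional[int] = None):
    gamma, q0, beta = p.gamma, p.q0, p.beta
    zeta0, Ka, mu, tau = p.zeta0, p.Ka, p.mu, p.tau
    lam, alpha = p.lam, p.alpha
    kd_h = p.kd / HOURS_PER_DAY
    R0 = p.R0
    calls = [0]

    def rhs(t, y):
        if max_calls is not None:
            calls[0] += 1
            if calls[0] > max_calls:
                raise _RhsBudgetExceeded()
        x, q, s, trc, trl, Q, lna = y
        R = R0 * np.exp(x)
        dP = protocol.pressure(t)
        dPdot = protocol.pressure_rate(t)
        qdot = -gamma * (q * q - q0 * q0) * q + beta * 0.5 * (trc - trl)
        # dR/dt eliminated from the time-differentiated Laplace constraint
        denom = Ka * (0.5 + q) ** 2 + mu / tau - dP * R
        v = (trc / tau - (zeta0 + Ka * s) * qdot + dPdot * R) / denom
        return (
            v,
            qdot,
            v * (0.5 + q),
            (mu * v - trc) / tau,
            -trl / tau,
            0.5 * v - lam * (Q - alpha * q),
            v - kd_h,
        )

    def capacity(t, y):
        # terminal event: short-time elastic capacity exhausted
        R = R0 * np.exp(y[0])
        return (Ka * (0.5 + y[1]) ** 2 + mu / tau) - 1.01 * protocol.pressure(t) * R

    capacity.terminal = True
    capacity.direction = -1
    return rhs, capacity


def integrate_tube(protocol: PressureProtocol, p: ModelParams,
                   t_grid: Sequence[float], *, rtol: float = 1e-8,
                   method: str = "LSODA", check_laplace: bool = True,
                   on_instability: str = "raise",
                   max_rhs_calls: Optional[int] = 200_000) -> Trajectory:
    """Integrate the closed tube ODE system under a pressure protocol.

    ``t_grid`` are the requested output times (h); integration starts at the
    protocol's first segment (steady state at the culture pressure) and runs
    to ``max(t_grid)``.  Pressure changes are linear ramps of the protocol's
    ``ramp_duration``; a zero ramp duration invokes the instantaneous
    elastic ``pressure_jump``.

    Raises
    ------
    LaplaceInstabilityError
        when the short-time elastic capacity falls below the pressure load
        (``on_instability="truncate"`` returns the partial trajectory
        instead, flagged ``terminated_early``).
    IntegrationError
        on solver failure or Laplace-invariant violation.
    """
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    t_end = float(t_grid[-1])
    if t_grid[0] < protocol.t_start:
        raise ValueError("t_grid starts before the protocol span")

    p = p.with_zeta0_closure(protocol.dP0)
    state0 = initial_steady_state(protocol.dP0, p)
    rhs, capacity = _rhs_factory(p, protocol, max_calls=max_rhs_calls)

    # integration breakpoints: start/end of every pressure change
    breaks = [protocol.t_start]
    jumps_at = set()
    for (t_i, _) in protocol.segments[1:]:
        if t_i >= t_end:
            continue
        breaks.append(t_i)
        if protocol.ramp_duration > 0:
            breaks.append(min(t_i + protocol.ramp_duration, t_end))
        else:
            jumps_at.add(t_i)
    breaks.append(t_end)
    breaks = sorted(set(breaks))

    atol = [1e-10, 1e-10, 1e-10, 1e-12, 1e-12, 1e-10, 1e-10]
    y = np.array([0.0, state0.q, state0.s, state0.tr_c, state0.tr_l,
                  state0.Q, 0.0])
    pieces, jump_records = [], []
    terminated = False
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if lo in jumps_at:
            dP_new = protocol.pressure(lo + 1e-12)
            st = TubeState(t=lo, R=p.R0 * np.exp(y[0]), q=y[1], s=y[2],
                           tr_c=y[3], tr_l=y[4], Q=y[5],
                           a_rel=float(np.exp(y[6])))
            st = pressure_jump(st, dP_new, p)
            y = np.array([np.log(st.R / p.R0), st.q, st.s, st.tr_c,
                          st.tr_l, st.Q, np.log(st.a_rel)])
            jump_records.append((lo, st))
        try:
            sol = solve_ivp(rhs, (lo, hi), y, method=method, rtol=rtol,
                            atol=atol, dense_output=True, events=capacity,
                            max_step=max((hi - lo) / 4, 1e-3))
        except _RhsBudgetExceeded:
            raise IntegrationError(
                f"integration stalled on [{lo}, {hi}]: step budget exhausted")
        if sol.status == 1:  # capacity event fired
            pieces.append((lo, sol.t[-1], sol.sol))
            terminated = True
            t_fail = sol.t[-1]
            break
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{lo}, {hi}]: {sol.message}",
                last_state=(sol.t[-1], sol.y[:, -1]))
        pieces.append((lo, hi, sol.sol))
        y = sol.y[:, -1]

    t_last = pieces[-1][1]
    keep = t_grid[t_grid <= t_last + 1e-12]
    if keep.size == 0:
        keep = np.array([t_last])
    traj = _assemble(keep, pieces, jump_records, p, protocol,
                     terminated=terminated)
    if terminated:
        msg = (f"Laplace instability: elastic capacity exhausted at "
               f"t = {t_fail:.3g} h")
        if on_instability == "raise":
            raise LaplaceInstabilityError(msg, trajectory=traj, t_fail=t_fail)
        traj.termination_reason = msg
        return traj
    if check_laplace:
        resid = traj.laplace_residual()
        if np.any(resid > 1e-6):
            raise IntegrationError(
                f"Laplace invariant violated: max residual {resid.max():.3g}")
    return traj


def _assemble(t_grid, pieces, jump_records, p, protocol, terminated=False):
    ys = np.empty((7, t_grid.size))
    for j, tj in enumerate(t_grid):
        for (lo, hi, dense) in pieces:
            if lo <= tj <= hi:
                ys[:, j] = dense(tj)
                break
        else:
            raise IntegrationError(f"output time {tj} outside solution span")
    return Trajectory(
        t=t_grid, R=p.R0 * np.exp(ys[0]), q=ys[1], s=ys[2], tr_c=ys[3],
        tr_l=ys[4], Q=ys[5], a_rel=np.exp(ys[6] - ys[6, 0]), params=p,
        protocol=protocol, terminated_early=terminated,
        _pieces=pieces, _jumps=jump_records,
    )
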