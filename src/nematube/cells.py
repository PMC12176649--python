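"""Cell-scale observables slaved to the tube dynamics.

Mean cell area follows the isotropic shear decomposition
``(1/a) da/dt = (1/R) dR/dt - kd`` (no apoptosis, constant division rate),
with closed form ``a(t) = a0 (R/R0) exp(-kd t)``.  Cell elongation follows
an anisotropic shear decomposition where rearrangements relax Q toward the
actin-set preferred value: ``dQ/dt = (1/2) dlnR/dt - lam (Q - alpha q)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .params import ModelParams
from .tube import Trajectory, HOURS_PER_DAY

__all__ = [
    "CellObservables", "area_trajectory", "elongation_trajectory",
    "infer_kd_from_area", "edu_to_rate", "fit_density_dependence",
]


@dataclass
class CellObservables:
    t: np.ndarray
    a_rel: np.ndarray
    Q: np.ndarray
    Qn: Optional[np.ndarray] = None


class InferenceError(RuntimeError):
    pass


def area_trajectory(t, R, kd: float, a0: float = 1.0):
    """Mean cell area under the isotropic shear decomposition.

    Closed form of ``(1/a) da/dt = dlnR/dt - kd``:
    ``a(t) = a0 * (R(t)/R(t0)) * exp(-kd (t - t0))`` with ``kd`` in d^-1
    and ``t`` in hours.
    """
    t = np.asarray(t, float)
    R = np.asarray(R, float)
    if np.any(R <= 0):
        raise ValueError("radii must be positive")
    return a0 * (R / R[0]) * np.exp(-kd * (t - t[0]) / HOURS_PER_DAY)


def elongation_trajectory(traj: Trajectory, p: ModelParams,
                          Q_init: Optional[float] = None,
                          lam: Optional[float] = None,
                          alpha: Optional[float] = None,
                          n_sub: int = 40) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate cell elongation along a tube trajectory.

    ``dQ/dt = dlnR/dt / 2 - lam (Q - alpha q)``, solved with an exponential
    (integrating-factor) scheme on a refined grid so the advective kick of
    fast pressure ramps is captured.  ``Q_init`` defaults to the slaved
    value ``alpha * q(t0)``.  ``lam``/``alpha`` override the parameter set;
    in the ``lam = 0`` limit Q is purely advected (``dQ = ln(R+/R-)/2``),
    for large ``lam`` it is slaved to ``alpha*q``.
    """
    out_idx = [0]
    segs = [np.array([traj.t[0]])]
    for i in range(len(traj.t) - 1):
        seg = np.linspace(traj.t[i], traj.t[i + 1], n_sub + 1)[1:]
        segs.append(seg)
        out_idx.append(out_idx[-1] + seg.size)
    tt = np.concatenate(segs)
    out_idx = np.asarray(out_idx)
    xs = traj.states_at(tt)
    lnR, q = xs[0], xs[1]
    lam = p.lam if lam is None else lam
    alpha = p.alpha if alpha is None else alpha
    if Q_init is None:
        Q_init = alpha * q[0]
    Q = np.empty_like(tt)
    Q[0] = Q_init
    if lam == 0.0:
        Q = Q_init + 0.5 * (lnR - lnR[0])
    else:
        # exact update for piecewise-linear lnR(t) and q(t)
        for i in range(1, tt.size):
            dt = tt[i] - tt[i - 1]
            e = np.exp(-lam * dt)
            adv = 0.5 * (lnR[i] - lnR[i - 1]) / dt
            qbar = 0.5 * (q[i] + q[i - 1])
            Qinf = qbar * alpha + adv / lam
            Q[i] = Qinf + (Q[i - 1] - Qinf) * e
    return traj.t, Q[out_idx]


def infer_kd_from_area(t, a_rel, R) -> Tuple[float, float]:
    """Division rate from area and radius series by the shear decomposition.

    Rearranging the closed form, ``-ln[(a/a0) (R0/R)] = kd * t``; the slope
    of a least-squares regression through the pooled points gives ``kd``
    (d^-1) with its standard error.  ``a_rel`` may be 1-D or
    (n_replicates, n_times).
    """
    t = np.asarray(t, float)
    a = np.atleast_2d(np.asarray(a_rel, float))
    R = np.asarray(R, float)
    if a.shape[-1] != t.size or R.size != t.size:
        raise InferenceError("series must share time points")
    if t.size < 3:
        raise InferenceError("need at least 3 time points")
    if np.any(a <= 0) or np.any(R <= 0):
        raise InferenceError("areas and radii must be positive")
    y = -np.log(a * (R[0] / R)[None, :])
    td = np.broadcast_to(t / HOURS_PER_DAY, y.shape)
    res = stats.linregress(td.ravel(), y.ravel())
    return float(res.slope), float(res.stderr)


def edu_to_rate(n_pos: int, n_total: int, T: float,
                convention: str = "exponential") -> float:
    """Division rate (d^-1) from an EdU pulse of duration ``T`` hours.

    With Poissonian divisions the unlabelled fraction decays exponentially,
    so ``kd = -ln(1 - f) / T`` for positive fraction ``f``; the linear
    small-fraction convention ``kd = f / T`` is also available.
    """
    if not 0 <= n_pos <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_pos <= n_total with n_total > 0")
    if T <= 0:
        raise ValueError("pulse duration must be positive")
    f = n_pos / n_total
    if convention == "linear":
        return f / (T / HOURS_PER_DAY)
    if f >= 1.0:
        raise ValueError("all nuclei labelled: rate unbounded")
    return -np.log1p(-f) / (T / HOURS_PER_DAY)


def fit_density_dependence(density, kd, p0=None):
    """Fit ``kd = k_max * exp(-rho / rho_c)`` to density/rate pairs.

    Returns ``(k_max, rho_c, residual)`` where residual is the sum of
    squared deviations.  Near-constant data drive ``rho_c`` to infinity;
    this degeneracy is flagged by returning ``rho_c = inf``.
    """
    density = np.asarray(density, float)
    kd = np.asarray(kd, float)
    if density.size < 4:
        raise InferenceError("need at least 4 density/rate pairs")
    if np.any(density <= 0) or np.any(kd < 0):
        raise InferenceError("densities must be positive, rates non-negative")
    span = kd.max() - kd.min()
    if span < 1e-12 * max(kd.max(), 1e-30):
        return float(kd.mean()), float("inf"), 0.0
    if p0 is None:
        # log-linear start
        pos = kd > 0
        b, a = np.polyfit(density[pos], np.log(kd[pos]), 1)
        p0 = (float(np.exp(a)), float(-1.0 / b) if b < 0 else density.mean())
    try:
        popt, _ = curve_fit(lambda x, kmax, rc: kmax * np.exp(-x / rc),
                            density, kd, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise InferenceError(f"density fit failed to converge: {exc}") from exc
    resid = float(np.sum((kd - popt[0] * np.exp(-density / popt[1])) ** 2))
    return float(popt[0]), float(popt[1]), resid
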