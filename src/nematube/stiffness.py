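"""Monolayer stiffness from pressure-ramp stress-strain curves.

The monolayer is treated as a thin incompressible shell of thickness ``h``
inflated at fixed tube length (plane strain, ``lam_z = 1``).  For a
circumferential stretch ``lam`` the first invariant is
``I1 = lam^2 + 1 + lam^-2``; a Gent material stiffens without bound as
``I1 - 3`` approaches the limiting parameter ``Jm``, reproducing the
threshold strain of roughly 20% seen in ramp experiments.  The hoop Cauchy
stress is

    sigma = (E/3) * Jm * (lam^2 - lam^-2) / (Jm - (I1 - 3)),

and the membrane tension ``t = sigma * h / lam`` (incompressible thinning).
The small-strain limit is ``t = (4/3) E h eps``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = ["ShellParams", "StressStrainCurve", "gent_tension",
           "simulate_ramp", "infer_linear_modulus", "fit_gent_curve",
           "LINEAR_STRAIN_CUTOFF"]

#: Strain separating the linear from the stiffening regime.
LINEAR_STRAIN_CUTOFF = 0.2


class StiffnessError(RuntimeError):
    pass


@dataclass(frozen=True)
class ShellParams:
    """Elastic shell: Young's modulus E (Pa), thickness h (m), Gent limit
    Jm, Poisson ratio nu, optional linear gel back-pressure per unit strain
    (Pa)."""

    E: float = 30e3
    h: float = 3.6e-6
    Jm: float = 0.35
    nu: float = 0.5
    gel_coeff: float = 0.0

    def __post_init__(self):
        if self.E <= 0 or self.h <= 0 or self.Jm <= 0:
            raise ValueError("E, h and Jm must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")

    @property
    def lam_max(self) -> float:
        """Limiting stretch where I1 - 3 reaches Jm: (lam-1/lam)^2 = Jm."""
        r = np.sqrt(self.Jm)
        return 0.5 * (r + np.sqrt(r * r + 4.0))


@dataclass
class StressStrainCurve:
    """Pressure-diameter pairs from a ramp experiment."""

    dP: np.ndarray
    D: np.ndarray
    D0_ref: float = 125e-6
    label: str = ""

    def __post_init__(self):
        self.dP = np.asarray(self.dP, float)
        self.D = np.asarray(self.D, float)
        if self.dP.shape != self.D.shape:
            raise ValueError("dP and D must have equal length")
        if np.any(np.diff(self.dP) < 0):
            raise ValueError("pressures must be non-decreasing")
        if np.any(self.D <= 0) or self.D0_ref <= 0:
            raise ValueError("diameters must be positive")

    @property
    def strain(self) -> np.ndarray:
        return self.D / self.D0_ref - 1.0


def gent_tension(lam, sp: ShellParams):
    """Membrane tension (N/m) of the Gent shell at circumferential stretch
    ``lam`` (plane strain, incompressible, thinning h/lam)."""
    lam = np.asarray(lam, float)
    if np.any(lam < 1):
        raise ValueError("stretch must be >= 1")
    I1m3 = lam ** 2 + lam ** -2 - 2.0
    if np.any(I1m3 >= sp.Jm):
        raise StiffnessError("limiting stretch exceeded: I1 - 3 >= Jm")
    sigma = (sp.E / 3.0) * sp.Jm * (lam ** 2 - lam ** -2) / (sp.Jm - I1m3)
    return sigma * sp.h / lam


def _pressure_of_stretch(lam, sp: ShellParams, D0: float):
    """Laplace pressure carried by the shell at stretch ``lam`` plus the
    optional linear gel back-pressure."""
    R = lam * D0 / 2.0
    return gent_tension(lam, sp) / R + sp.gel_coeff * (lam - 1.0)


def simulate_ramp(sp: ShellParams, D0: float, dP_grid) -> StressStrainCurve:
    """Forward-simulate a quasi-static pressure ramp.

    For each pressure the stretch solves
    ``dP = t_gent(lam) / (lam D0/2) + gel_coeff (lam - 1)`` on the stable
    (rising) branch by bracketed root finding; strain diverges as the Gent
    limit is approached.
    """
    dP_grid = np.asarray(dP_grid, float)
    if np.any(np.diff(dP_grid) < 0):
        raise ValueError("dP_grid must be non-decreasing")
    lam_hi = sp.lam_max
    lams = np.empty_like(dP_grid)
    for i, dP in enumerate(dP_grid):
        if dP <= 0:
            lams[i] = 1.0
            continue
        f = lambda lam: _pressure_of_stretch(lam, sp, D0) - dP
        # stable branch: pressure rises with stretch up to its maximum
        # (stay strictly inside the Gent limit)
        grid = 1.0 + (lam_hi - 1.0) * np.linspace(0.0, 1.0 - 1e-9, 400)[1:] ** 2
        pr = np.array([_pressure_of_stretch(g, sp, D0) for g in grid])
        top = np.argmax(pr)
        if pr[top] < dP:
            raise StiffnessError(
                f"no stable solution at dP = {dP:.4g} Pa (pressure maximum "
                f"{pr[top]:.4g} Pa on the rising branch)")
        j = np.searchsorted(pr[: top + 1], dP)
        lo = grid[j - 1] if j > 0 else 1.0
        lams[i] = brentq(f, lo, grid[j], xtol=1e-14, rtol=1e-15)
    return StressStrainCurve(dP=dP_grid, D=lams * D0, D0_ref=D0)


_E_CONVENTIONS = {
    # surface stiffness S = d(dP*R)/d(eps) -> Young's modulus
    "plane_strain": lambda S, h, nu: 3.0 * S / (4.0 * h),
    "simple": lambda S, h, nu: S / h,
    "plate": lambda S, h, nu: S * (1.0 - nu ** 2) / h,
}


def infer_linear_modulus(curve: StressStrainCurve, h: float, nu: float = 0.5,
                         convention: str = "plane_strain"):
    """Surface stiffness and Young's modulus from the linear regime.

    ``S = d(dP*R)/d(eps)`` by least squares over points with strain below
    the stiffening threshold; ``E`` follows from ``S`` under the chosen
    thin-shell convention (all three are reported).

    Returns a dict with keys ``S_Nm``, ``E_Pa`` (chosen convention) and
    ``E_Pa_by_convention``.
    """
    eps = curve.strain
    keep = eps < LINEAR_STRAIN_CUTOFF
    if keep.sum() < 2:
        raise StiffnessError("need >= 2 points in the linear regime")
    load = curve.dP[keep] * curve.D[keep] / 2.0
    slope, _ = np.polyfit(eps[keep], load, 1)
    S = float(slope)
    by_conv = {k: f(S, h, nu) for k, f in _E_CONVENTIONS.items()}
    return {"S_Nm": S, "E_Pa": by_conv[convention],
            "E_Pa_by_convention": by_conv, "n_points": int(keep.sum())}


def fit_gent_curve(curve: StressStrainCurve, h: float,
                   Jm_max: float = 10.0):
    """Nonlinear least squares of the Gent ramp model to a measured curve.

    Fits ``(E, Jm)`` by matching predicted diameters; starts from the
    linear-regime slope.  Returns ``(E, Jm, residual)``; a ``Jm`` estimate
    at the bound flags effectively linear data.
    """
    if curve.dP.size < 6:
        raise StiffnessError("need >= 6 points spanning both regimes")
    D0 = curve.D0_ref
    try:
        E0 = infer_linear_modulus(curve, h)["E_Pa"]
    except StiffnessError:
        E0 = 30e3
    eps_max = curve.strain.max()
    Jm0 = min(max(2.5 * eps_max ** 2 * 4, 0.05), Jm_max / 2)

    def resid(theta):
        E, Jm = np.exp(theta)
        sp = ShellParams(E=E, h=h, Jm=Jm, gel_coeff=curve_gel)
        try:
            sim = simulate_ramp(sp, D0, curve.dP)
        except StiffnessError:
            return np.full(curve.dP.size, 1e3)
        return (sim.D - curve.D) / D0

    curve_gel = 0.0
    sol = least_squares(resid, np.log([E0, Jm0]),
                        bounds=(np.log([1e1, 1e-3]), np.log([1e7, Jm_max])),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise StiffnessError(f"Gent fit failed: {sol.message}")
    E, Jm = np.exp(sol.x)
    return {"E_Pa": float(E), "Jm": float(Jm),
            "residual": float(2 * sol.cost),
            "linear_degenerate": bool(Jm > 0.95 * Jm_max)}
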