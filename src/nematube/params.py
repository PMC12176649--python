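"""Parameter containers for the endothelial-tube model.

Units are SI internally (m, Pa, N/m) with time in hours; the cell division
rate ``kd`` is kept in d^-1, the unit in which it is usually reported, and
converted at use sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Constitutive constants of the active nematic tube model.

    Parameters
    ----------
    gamma : float
        Relaxation rate of the actin nematic order parameter (h^-1).
    q0 : float
        Preferred magnitude of nematic order, in (0, 0.5].
    beta : float
        Mechanosensitive coupling of nematic order to the traceless
        residual tension ((N/m)^-1 h^-1).
    zeta0 : float, optional
        Active (deformation-independent) fibre tension scale (N/m).  When
        None it is closed from the initial Laplace balance
        ``zeta0 = dP0 * R0 / (1/2 - q0)`` at the culture pressure.
    Ka : float
        Two-dimensional elastic modulus of the actin fibre network (N/m).
    mu : float
        Two-dimensional tissue viscosity of the Maxwell element (N h/m).
    tau : float
        Maxwell viscoelastic relaxation time (h).  The short-time elastic
        modulus is ``K = mu / tau``.
    kd : float
        Cell division rate (d^-1).
    lam : float
        Relaxation rate of cell elongation toward its actin-set preferred
        value (h^-1).
    alpha : float
        Preferred cell elongation per unit actin nematic order
        (dimensionless).
    R0 : float
        Reference tube radius at the culture pressure (m).
    h_mono : float
        Monolayer thickness (m); used by the shell-stiffness module.
    """

    gamma: float = 1.3
    q0: float = 0.25
    beta: float = 15.0
    zeta0: Optional[float] = None
    Ka: float = 0.22
    mu: float = 0.29
    tau: float = 1.0
    kd: float = 0.27
    lam: float = 4.0 / 3.0
    alpha: float = 0.7
    R0: float = 62.5e-6
    h_mono: float = 3.6e-6

    def __post_init__(self):
        for name in ("gamma", "zeta0", "Ka", "mu", "tau", "lam", "R0", "h_mono"):
            v = getattr(self, name)
            if name == "zeta0" and v is None:
                continue
            if not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        for name in ("kd", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0 < self.q0 <= 0.5:
            raise ParameterError(f"q0 must lie in (0, 0.5], got {self.q0!r}")

    @property
    def K(self) -> float:
        """Short-time elastic modulus of the Maxwell element, mu/tau (N/m)."""
        return self.mu / self.tau

    def with_zeta0_closure(self, dP0: float) -> "ModelParams":
        """Return params with ``zeta0`` fixed by the Laplace balance at ``dP0``.

        At the pre-step steady state the fibres are longitudinal
        (q = -q0, s = 0) and the residual tension vanishes, so Laplace's law
        reads ``dP0 * R0 = zeta0 * (1/2 - q0)``.
        """
        if dP0 <= 0:
            raise ParameterError("culture pressure must be positive")
        z = dP0 * self.R0 / (0.5 - self.q0)
        if self.zeta0 is not None:
            if abs(self.zeta0 - z) > 1e-6 * z:
                raise ParameterError(
                    f"supplied zeta0={self.zeta0} inconsistent with Laplace "
                    f"closure {z:.6g} at dP0={dP0} Pa"
                )
            return self
        return replace(self, zeta0=z)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PressureProtocol:
    """Piecewise-constant luminal pressure with linear ramps between levels.

    ``segments`` is an ordered list of ``(start_time_h, dP_Pa)`` pairs; the
    first segment defines the initial (culture) pressure and the time origin
    of integration.  Each later segment begins a linear ramp of duration
    ``ramp_duration`` from the previous level.  ``ramp_duration = 0`` means
    an instantaneous elastic jump.
    """

    segments: tuple = ((0.0, 150.0),)
    ramp_duration: float = 1.0 / 60.0

    def __post_init__(self):
        segs = tuple((float(t), float(p)) for t, p in self.segments)
        object.__setattr__(self, "segments", segs)
        times = [t for t, _ in segs]
        if len(segs) == 0:
            raise ParameterError("protocol needs at least one segment")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("segment start times must be strictly increasing")
        if any(p < 0 for _, p in segs):
            raise ParameterError("pressures must be non-negative")
        if self.ramp_duration < 0:
            raise ParameterError("ramp_duration must be non-negative")

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def dP0(self) -> float:
        """Initial (culture) pressure in Pa."""
        return self.segments[0][1]

    def pressure(self, t: float) -> float:
        """Luminal pressure at time ``t`` (linear interpolation on ramps)."""
        p = self.segments[0][1]
        for t_i, p_i in self.segments[1:]:
            if t < t_i:
                break
            if self.ramp_duration > 0 and t < t_i + self.ramp_duration:
                frac = (t - t_i) / self.ramp_duration
                p = p + (p_i - p) * frac
                break
            p = p_i
        return p

    def pressure_rate(self, t: float) -> float:
        """d(dP)/dt at time ``t`` (Pa/h); nonzero only on ramps."""
        p = self.segments[0][1]
        for t_i, p_i in self.segments[1:]:
            if t < t_i:
                return 0.0
            if self.ramp_duration > 0 and t < t_i + self.ramp_duration:
                return (p_i - p) / self.ramp_duration
            p = p_i
        return 0.0


def step_protocol(dP_high: float = 650.0, dP_low: float = 150.0,
                  t_step: float = 0.0, lead: float = 1.0,
                  ramp_duration: float = 1.0 / 60.0) -> PressureProtocol:
    """The study's canonical protocol: culture at ``dP_low``, step to
    ``dP_high`` at ``t_step`` (ramped over ``ramp_duration``), after a
    steady lead-in of ``lead`` hours."""
    return PressureProtocol(
        segments=((t_step - lead, dP_low), (t_step, dP_high)),
        ramp_duration=ramp_duration,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate-noise configuration of the synthetic-data generator."""

    sd_R_rel: float = 0.02
    sd_q: float = 0.02
    sd_Q: float = 0.02
    sd_area_rel: float = 0.05
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self):
        for name in ("sd_R_rel", "sd_q", "sd_Q", "sd_area_rel"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be at least 1")

    def replace(self, **kwargs) -> "NoiseSpec":
        return replace(self, **kwargs)


#: Observation schedule of the fixed-pressure assay (h).
OBSERVATION_TIMES = (0.0, 7.0, 24.0, 56.0)

#: Channel mean pressures of the pressure-magnitude assay (Pa).
PRESSURE_LEVELS = (150.0, 450.0, 650.0, 850.0)
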