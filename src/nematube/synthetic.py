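"""Seeded synthetic datasets with the statistical structure of the
microstretcher measurements.

The generator runs the forward tube model under a pressure protocol and
emulates what the experiment records: replicate tube-radius time series
(0.5 h sampling), orientation-angle samples for actin fibres, junctions and
nuclei at the observation times {0, 7, 24, 56} h, normalized mean cell
areas, and binomial EdU counts from an 8 h pulse.  Every generator is a
pure function of its inputs and seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .params import (ModelParams, NoiseSpec, PressureProtocol,
                     OBSERVATION_TIMES, step_protocol)
from .order import AngleSet, nematic_order, cell_order, ALPHA_Q_DEFAULT
from .stiffness import ShellParams, StressStrainCurve, simulate_ramp
from .tube import Trajectory, integrate_tube

__all__ = ["SyntheticDataset", "sample_angles", "generate_observations",
           "generate_edu", "generate_ramp", "vonmises_concentration"]

RADIUS_SAMPLING_H = 0.5
EDU_PULSE_H = 8.0
ANGLES_PER_SET = 500


def vonmises_concentration(order: float) -> float:
    """Concentration kappa of a von Mises distribution of doubled angles
    whose population nematic order magnitude equals ``order``.

    Solves the Bessel-ratio equation ``I1(kappa)/I0(kappa) = 2*order``.
    """
    if not 0 <= order < 0.5:
        raise ValueError("order magnitude must lie in [0, 0.5)")
    if order == 0:
        return 0.0
    target = 2.0 * order
    f = lambda k: i1e(k) / i0e(k) - target
    hi = 4.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("order too close to 1/2")
    return brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12)


def sample_angles(q_target: float, n: int, seed, label: str = "actin") -> AngleSet:
    """Draw ``n`` orientation angles whose population order is ``q_target``.

    Doubled angles 2*theta follow a von Mises distribution centred on the
    circumferential (180 deg) or longitudinal (0 deg) doubled axis for
    positive / negative targets; the sample estimate converges to
    ``q_target`` as n grows.
    """
    if abs(q_target) >= 0.5:
        raise ValueError("|q_target| must be < 1/2")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kappa = vonmises_concentration(abs(q_target))
    mu = np.pi if q_target > 0 else 0.0
    if kappa == 0.0:
        phi = rng.uniform(-np.pi, np.pi, size=n)
    else:
        phi = rng.vonmises(mu, kappa, size=n)
    theta = np.rad2deg(phi) / 2.0
    return AngleSet(theta, label=label)


def generate_edu(kd: float, T: float, n_cells: int, seed,
                 n_replicates: int = 1):
    """Binomial EdU counts: each of ``n_cells`` nuclei is labelled with
    probability ``1 - exp(-kd * T)`` (kd in d^-1, T in hours).

    Returns an array of shape (n_replicates, 2) of (n_pos, n_total).
    """
    if kd < 0 or T <= 0 or n_cells < 1:
        raise ValueError("invalid EdU assay configuration")
    rng = np.random.default_rng(seed)
    f = 1.0 - np.exp(-kd * T / 24.0)
    n_pos = rng.binomial(n_cells, f, size=n_replicates)
    return np.column_stack([n_pos, np.full(n_replicates, n_cells)])


def generate_ramp(sp: ShellParams, D0: float, dP_grid, noise_sd_D: float,
                  seed) -> StressStrainCurve:
    """Forward Gent ramp plus Gaussian diameter noise (m)."""
    curve = simulate_ramp(sp, D0, dP_grid)
    rng = np.random.default_rng(seed)
    D = curve.D + rng.normal(0.0, noise_sd_D, size=curve.D.size)
    return StressStrainCurve(dP=curve.dP, D=D, D0_ref=D0, label="synthetic")


@dataclass
class SyntheticDataset:
    """A complete synthetic observation set for one pressure protocol."""

    t_radius: np.ndarray                 # radius sampling times (h)
    radius_rel: np.ndarray               # (n_rep, n_t) noisy R/R0
    t_obs: np.ndarray                    # angle/area observation times (h)
    angles: Dict[Tuple[str, float], AngleSet]
    a_obs: np.ndarray                    # (n_rep, n_obs) noisy a/a0
    edu: np.ndarray                      # (n_rep, 2) EdU counts
    params: ModelParams
    protocol: PressureProtocol
    noise: NoiseSpec
    trajectory: Trajectory = None

    @property
    def q_obs(self) -> np.ndarray:
        """Actin nematic order estimated from the angle samples."""
        return np.array([nematic_order(self.angles[("actin", t)])
                         for t in self.t_obs])

    @property
    def Q_obs(self) -> np.ndarray:
        """Cell elongation estimated from the junction angle samples."""
        return np.array([cell_order(self.angles[("junction", t)])
                         for t in self.t_obs])

    @property
    def Qn_obs(self) -> np.ndarray:
        return np.array([cell_order(self.angles[("nucleus", t)])
                         for t in self.t_obs])

    @property
    def radius_rel_mean(self) -> np.ndarray:
        return self.radius_rel.mean(axis=0)

    @property
    def a_obs_mean(self) -> np.ndarray:
        return self.a_obs.mean(axis=0)


def generate_observations(p: ModelParams, protocol: PressureProtocol = None,
                          ns: NoiseSpec = None, *,
                          t_end: float = 56.0,
                          t_obs=OBSERVATION_TIMES,
                          n_angles: int = ANGLES_PER_SET,
                          alpha_Q: float = ALPHA_Q_DEFAULT,
                          rtol: float = 1e-8) -> SyntheticDataset:
    """Run the forward model and dress it with measurement noise.

    Radius and area replicates receive independent Gaussian noise with the
    NoiseSpec standard deviations; angle sets are drawn from von Mises
    distributions matching the model's actin order ``q(t)``, the junction
    order ``alpha*q(t)/alpha_Q`` (so the calibrated cell order recovers the
    model's Q when slaving is fast) and the nucleus order ``alpha*q(t)``.
    Bit-identical given (params, protocol, noise.seed).
    """
    if protocol is None:
        protocol = step_protocol()
    if ns is None:
        ns = NoiseSpec()
    rng = np.random.default_rng(ns.seed)

    t_grid = np.arange(0.0, t_end + 1e-9, RADIUS_SAMPLING_H)
    t_obs = np.asarray(t_obs, float)
    t_all = np.unique(np.concatenate([t_grid, t_obs]))
    traj = integrate_tube(protocol, p, t_all, rtol=rtol)
    p = traj.params  # zeta0 closed

    i_grid = np.searchsorted(t_all, t_grid)
    i_obs = np.searchsorted(t_all, t_obs)
    R_rel = traj.R[i_grid] / p.R0
    radius_rel = (R_rel[None, :]
                  + rng.normal(0.0, ns.sd_R_rel,
                               size=(ns.n_replicates, R_rel.size)))

    a_model = traj.a_rel[i_obs]
    a_obs = (a_model[None, :]
             + rng.normal(0.0, ns.sd_area_rel,
                          size=(ns.n_replicates, a_model.size)))

    angles: Dict[Tuple[str, float], AngleSet] = {}
    for j, t in enumerate(t_obs):
        q_t = traj.q[i_obs[j]]
        Q_t = traj.Q[i_obs[j]]
        targets = {
            "actin": q_t,
            "junction": Q_t / alpha_Q,
            "nucleus": Q_t,
        }
        for label, target in targets.items():
            target = float(np.clip(target, -0.4999, 0.4999))
            sub = rng.integers(0, 2 ** 31 - 1)
            angles[(label, float(t))] = sample_angles(target, n_angles, sub,
                                                      label=label)

    edu = generate_edu(p.kd, EDU_PULSE_H, 1000,
                       rng.integers(0, 2 ** 31 - 1),
                       n_replicates=ns.n_replicates)

    return SyntheticDataset(
        t_radius=t_grid, radius_rel=radius_rel, t_obs=t_obs, angles=angles,
        a_obs=a_obs, edu=edu, params=p, protocol=protocol, noise=ns,
        trajectory=traj,
    )
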