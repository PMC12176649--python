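"""Nematic order parameters from orientation-angle samples.

Angles are measured in degrees from the tube's longitudinal axis and folded
into the half-open range (-90, 90]; the nematic symmetry theta == theta+180
makes only even circular moments meaningful.  The scalar order parameter is
the circumferential component of the orientation tensor,

    q = -<cos 2*theta> / 2,

so +0.5 is fully circumferential, -0.5 fully longitudinal and 0 isotropic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["AngleSet", "nematic_order", "cell_order", "affine_advect",
           "shear_deltaQ", "angle_histogram", "ALPHA_Q_DEFAULT"]

#: Calibration factor mapping junction-staining order to cell elongation.
ALPHA_Q_DEFAULT = 0.8

_LABELS = ("actin", "junction", "nucleus", "brightfield")


def fold_angles(angles_deg) -> np.ndarray:
    """Fold arbitrary angles into (-90, 90] using nematic symmetry."""
    a = np.asarray(angles_deg, float)
    a = np.mod(a + 90.0, 180.0) - 90.0
    # map -90 (excluded) to +90 (included)
    a = np.where(a == -90.0, 90.0, a)
    return a


@dataclass
class AngleSet:
    """A sample of orientation angles (degrees from the longitudinal axis)."""

    angles: np.ndarray
    weights: Optional[np.ndarray] = None
    label: str = "actin"

    def __post_init__(self):
        self.angles = fold_angles(self.angles)
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != self.angles.shape:
                raise ValueError("weights must match angles in shape")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValueError("weights must be non-negative with positive sum")

    def __len__(self):
        return self.angles.size


def _mean_cos2(a: AngleSet) -> float:
    if len(a) == 0:
        raise ValueError("empty angle set")
    c = np.cos(2.0 * np.deg2rad(a.angles))
    if a.weights is None:
        return float(np.mean(c))
    return float(np.average(c, weights=a.weights))


def nematic_order(a: AngleSet) -> float:
    """Scalar nematic order q = -<cos 2 theta>/2 of an angle sample."""
    return -0.5 * _mean_cos2(a)


def cell_order(a: AngleSet, alpha_Q: float = ALPHA_Q_DEFAULT) -> float:
    """Cell-elongation order Q = alpha_Q * (-<cos 2 theta>/2).

    The junction-staining orientation under-reports cell elongation, hence
    the calibration factor ``alpha_Q`` (0.8 for junction input).  Nucleus
    input carries no factor.  Bright-field input overestimates the
    junction-based order by about a factor two, so its raw order is halved
    before applying ``alpha_Q``.
    """
    if not 0 < alpha_Q <= 1.5:
        raise ValueError("alpha_Q must lie in (0, 1.5]")
    raw = nematic_order(a)
    if a.label == "brightfield":
        raw = 0.5 * raw
    if a.label == "nucleus":
        return raw
    return alpha_Q * raw


def affine_advect(a: AngleSet, lam_theta: float) -> AngleSet:
    """Advect each orientation by a pure circumferential stretch.

    A line element at angle theta from the longitudinal axis maps to
    ``theta' = atan2(lam_theta * sin theta, cos theta)`` when the
    circumferential direction is stretched by ``lam_theta`` and the
    longitudinal direction is preserved.  This is the null model for fibre
    reorientation by tissue deformation alone.
    """
    if lam_theta <= 0:
        raise ValueError("stretch ratio must be positive")
    th = np.deg2rad(a.angles)
    th2 = np.arctan2(lam_theta * np.sin(th), np.cos(th))
    return AngleSet(np.rad2deg(th2), weights=a.weights, label=a.label)


def shear_deltaQ(R_minus, R_plus):
    """Cell-elongation change under homogeneous advection by a radius
    change: dQ = (1/2) ln(R+/R-)."""
    if np.any(np.asarray(R_minus) <= 0) or np.any(np.asarray(R_plus) <= 0):
        raise ValueError("radii must be positive")
    return 0.5 * np.log(np.asarray(R_plus) / R_minus)


def angle_histogram(a: AngleSet, bin_deg: float = 4.0):
    """Normalized probability distribution over (-90, 90] with left-open,
    right-closed bins of width ``bin_deg`` (must divide 180).

    Returns ``(bin_left, bin_right, prob)`` arrays.
    """
    nbins = 180.0 / bin_deg
    if bin_deg <= 0 or abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin width must divide 180 degrees")
    nbins = int(round(nbins))
    edges = -90.0 + bin_deg * np.arange(nbins + 1)
    # left-open right-closed: bin i is (edges[i], edges[i+1]]
    idx = np.ceil((a.angles - (-90.0)) / bin_deg).astype(int) - 1
    idx = np.clip(idx, 0, nbins - 1)
    w = a.weights if a.weights is not None else np.ones(len(a))
    prob = np.bincount(idx, weights=w, minlength=nbins)
    prob = prob / prob.sum()
    return edges[:-1], edges[1:], prob
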