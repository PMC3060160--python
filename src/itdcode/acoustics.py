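"""Interaural geometry: angle-to-ITD mapping and the ITD prior.

A sound source at interaural angle theta (0 = midline, +-pi/2 = fully
lateral) reaches the far ear with a path difference combining the chord
and the arc around the head, giving the classic free-field mapping

    tau(theta) = (d / 2c) * (theta + sin(theta)),

with inter-ear distance d and sound speed c.  The physiological ITD range
is [-tau_max, tau_max] with tau_max = tau(pi/2) = (d/2c)(pi/2 + 1).

Assuming sound sources with uniformly distributed dihedral angles makes
theta uniform on [-pi/2, pi/2]; pushing that density through the mapping
yields the ITD prior, which piles up at the lateral extremes because the
mapping flattens there (the derivative at +-90 deg is half the one at the
midline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: speed of airborne sound (m/s) at room temperature
DEFAULT_SOUND_SPEED = 343.0
#: effective gerbil inter-ear distance (m); yields tau_max of ~120 us
DEFAULT_INTER_EAR_DISTANCE = 0.032


@dataclass(frozen=True)
class HeadGeometry:
    """Inter-ear distance (m) and sound speed (m/s) of a listener."""

    inter_ear_distance: float = DEFAULT_INTER_EAR_DISTANCE
    sound_speed: float = DEFAULT_SOUND_SPEED

    def __post_init__(self):
        if self.inter_ear_distance <= 0 or self.sound_speed <= 0:
            raise ValueError("inter_ear_distance and sound_speed must be positive")

    @property
    def tau_max(self) -> float:
        """Largest accessible ITD in microseconds (source at +-90 deg)."""
        return angle_to_itd(np.pi / 2, self)

    def scaled(self, factor: float) -> "HeadGeometry":
        """Geometry with the inter-ear distance multiplied by ``factor``."""
        return HeadGeometry(self.inter_ear_distance * factor, self.sound_speed)


def angle_to_itd(theta, geom: HeadGeometry):
    """Map interaural angle (rad, in [-pi/2, pi/2]) to ITD in microseconds.

    Odd and strictly increasing in theta; positive angles (contralateral
    side) give positive ITDs.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(np.abs(th) > np.pi / 2 + 1e-12):
        raise ValueError("theta must lie in [-pi/2, pi/2]")
    scale = geom.inter_ear_distance / (2.0 * geom.sound_speed)
    out = scale * (th + np.sin(th)) * 1e6
    return float(out) if np.ndim(theta) == 0 else out


def itd_to_angle(tau_us, geom: HeadGeometry):
    """Numerical inverse of :func:`angle_to_itd` by monotone root finding.

    Accepts |tau| up to tau_max (microseconds); vectorized over tau.
    """
    tau = np.asarray(tau_us, dtype=float)
    tmax = geom.tau_max
    if np.any(np.abs(tau) > tmax * (1 + 1e-9) + 1e-9):
        raise ValueError(f"|tau| must not exceed tau_max = {tmax:.3f} us")

    def _inv(t):
        t = min(max(t, -tmax), tmax)
        if t == 0.0:
            return 0.0
        return brentq(
            lambda th: angle_to_itd(th, geom) - t,
            -np.pi / 2,
            np.pi / 2,
            xtol=1e-15,
            rtol=1e-14,
        )

    if tau.ndim == 0:
        return float(_inv(float(tau)))
    return np.array([_inv(float(t)) for t in tau.ravel()]).reshape(tau.shape)


@dataclass(frozen=True)
class ITDPrior:
    """Discrete prior over ITD bins on the physiological range.

    ``grid`` holds bin centers in microseconds, symmetric about zero;
    ``weights`` are bin probabilities summing to one, with p(tau)=p(-tau).
    """

    grid: np.ndarray
    weights: np.ndarray
    tau_max: float

    def __post_init__(self):
        w = np.asarray(self.weights)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def entropy_bits(self) -> float:
        """Shannon entropy of the discretized prior in bits."""
        w = self.weights[self.weights > 0]
        return float(-(w * np.log2(w)).sum())


def itd_prior(geom: HeadGeometry, n_grid: int = 201) -> ITDPrior:
    """Prior over ITD from uniformly distributed interaural angles.

    Each ITD bin receives the angular measure of its preimage under the
    mapping (bin-integrated change of variables), so the edge singularity
    of the pointwise Jacobian integrates to a finite, exactly normalized
    mass.  Weights are symmetrized to remove root-finding round-off.
    """
    if n_grid < 16:
        raise ValueError("n_grid must be >= 16")
    tmax = geom.tau_max
    edges = np.linspace(-tmax, tmax, n_grid + 1)
    theta_edges = itd_to_angle(edges, geom)
    w = np.diff(theta_edges) / np.pi
    w = 0.5 * (w + w[::-1])  # enforce exact tau -> -tau symmetry
    w = w / w.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ITDPrior(grid=centers, weights=w, tau_max=tmax)
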