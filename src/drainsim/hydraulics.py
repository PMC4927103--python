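"""Closed-form van Genuchten-Mualem constitutive relations.

These are the soil-water retention and unsaturated-conductivity functions
used throughout the package: by the 2D flow solver, by the 1D steady-profile
surrogate used in calibration tests, and by the analytic unit-gradient
oracle.  Pressure head ``h`` is in cm with ``h < 0`` meaning suction and
``h >= 0`` meaning saturation; conductivities are in cm/day; water contents
are volumetric (cm^3 cm^-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VanGenuchtenParams",
    "ParameterError",
    "water_content_from_head",
    "effective_saturation",
    "saturation_from_head",
    "head_from_saturation",
    "conductivity_from_saturation",
    "conductivity_from_head",
    "water_capacity",
    "unit_gradient_state",
    "UnitGradientState",
]

_SE_EPS = 1e-12  # clip inside Mualem's K(Se) to avoid 0**negative


class ParameterError(ValueError):
    """Invalid van Genuchten parameter set."""


@dataclass(frozen=True)
class VanGenuchtenParams:
    """Retention/conductivity parameter set for one porous material.

    Parameters
    ----------
    theta_r, theta_s :
        Residual and saturated volumetric water content (cm^3 cm^-3).
    alpha :
        Inverse air-entry value (1/cm).
    n :
        Pore-size distribution index (-), must exceed 1.  The Mualem
        constraint ``m = 1 - 1/n`` is applied; ``m`` is never stored.
    Ks :
        Saturated hydraulic conductivity (cm/day).
    l :
        Pore-connectivity exponent (-), 0.5 by convention.
    """

    theta_r: float
    theta_s: float
    alpha: float
    n: float
    Ks: float
    l: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ParameterError(
                f"require 0 <= theta_r < theta_s <= 1, got "
                f"theta_r={self.theta_r}, theta_s={self.theta_s}"
            )
        if self.n <= 1.0:
            raise ParameterError(f"n must be > 1, got {self.n}")
        if self.alpha <= 0.0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.Ks <= 0.0:
            raise ParameterError(f"Ks must be > 0, got {self.Ks}")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


def water_content_from_head(h, p: VanGenuchtenParams):
    """theta(h): van Genuchten retention curve.

    Returns ``theta_s`` for ``h >= 0``; strictly increasing in h for h < 0;
    bounded in [theta_r, theta_s].  Accepts scalars or arrays.
    """
    h = np.asarray(h, dtype=float)
    ah = np.abs(p.alpha * np.minimum(h, 0.0))
    theta = p.theta_r + (p.theta_s - p.theta_r) * (1.0 + ah**p.n) ** (-p.m)
    return theta if theta.ndim else float(theta)


def effective_saturation(theta, p: VanGenuchtenParams, tol: float = 1e-9):
    """Se = (theta - theta_r) / (theta_s - theta_r), the linear map to [0, 1].

    Values outside [theta_r, theta_s] by more than ``tol`` raise; smaller
    excursions (solver round-off) are clipped.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < p.theta_r - tol) or np.any(theta > p.theta_s + tol):
        raise ValueError(
            f"theta outside [{p.theta_r}, {p.theta_s}] beyond tolerance {tol}"
        )
    se = (theta - p.theta_r) / (p.theta_s - p.theta_r)
    se = np.clip(se, 0.0, 1.0)
    return se if se.ndim else float(se)


def saturation_from_head(h, p: VanGenuchtenParams):
    """Se(h) = [1 + |alpha h|^n]^(-m) for h < 0, else 1."""
    h = np.asarray(h, dtype=float)
    ah = np.abs(p.alpha * np.minimum(h, 0.0))
    se = (1.0 + ah**p.n) ** (-p.m)
    return se if se.ndim else float(se)


def head_from_saturation(se, p: VanGenuchtenParams):
    """Inverse retention curve: h(Se), h = 0 at Se = 1."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0.0) or np.any(se > 1.0):
        raise ValueError("Se must lie in (0, 1]")
    h = -(1.0 / p.alpha) * (se ** (-1.0 / p.m) - 1.0) ** (1.0 / p.n)
    return h if h.ndim else float(h)


def conductivity_from_saturation(se, p: VanGenuchtenParams):
    """Mualem conductivity K(Se) = Ks * Se^l * [1 - (1 - Se^(1/m))^m]^2."""
    se = np.asarray(se, dtype=float)
    if np.any(se < 0.0) or np.any(se > 1.0):
        raise ValueError("Se must lie in [0, 1]")
    sec = np.clip(se, _SE_EPS, 1.0 - _SE_EPS)
    k = p.Ks * sec**p.l * (1.0 - (1.0 - sec ** (1.0 / p.m)) ** p.m) ** 2
    # exact endpoints
    k = np.where(se >= 1.0, p.Ks, np.where(se <= 0.0, 0.0, k))
    return k if k.ndim else float(k)


def conductivity_from_head(h, p: VanGenuchtenParams):
    return conductivity_from_saturation(saturation_from_head(h, p), p)


def water_capacity(h, p: VanGenuchtenParams):
    """C(h) = d theta / dh, analytic; zero for h >= 0."""
    h = np.asarray(h, dtype=float)
    hn = np.minimum(h, -1e-300)
    ah = np.abs(p.alpha * hn)
    c = (
        (p.theta_s - p.theta_r)
        * p.m
        * p.n
        * p.alpha
        * ah ** (p.n - 1.0)
        * (1.0 + ah**p.n) ** (-p.m - 1.0)
    )
    c = np.where(h >= 0.0, 0.0, c)
    return c if c.ndim else float(c)


@dataclass(frozen=True)
class UnitGradientState:
    """Steady gravity-driven (unit-gradient) unsaturated state."""

    h: float
    theta: float
    wfps: float
    Se: float


class InfeasibleUnitGradientError(ValueError):
    """Requested steady flux exceeds Ks (ponding regime)."""


def unit_gradient_state(q: float, p: VanGenuchtenParams) -> UnitGradientState:
    """Unique unsaturated state carrying a steady downward flux ``q``.

    Under a unit hydraulic gradient (gravity drainage, dh/dz = 0) the Darcy
    flux equals the unsaturated conductivity, so the state solves
    ``K(Se) = q``.  WFPS is theta/theta_s.  Serves as the analytic oracle for
    the interior of a homogeneous column far from boundaries.
    """
    if q <= 0.0:
        raise ValueError("q must be positive")
    if q > p.Ks:
        raise InfeasibleUnitGradientError(
            f"flux {q} exceeds Ks={p.Ks}: no unit-gradient solution (ponding)"
        )
    if q == p.Ks:
        return UnitGradientState(0.0, p.theta_s, 1.0, 1.0)

    from scipy.optimize import brentq

    se = brentq(
        lambda s: conductivity_from_saturation(s, p) - q,
        _SE_EPS,
        1.0,
        xtol=1e-14,
        rtol=1e-14,
    )
    theta = p.theta_r + se * (p.theta_s - p.theta_r)
    return UnitGradientState(
        h=head_from_saturation(se, p),
        theta=theta,
        wfps=theta / p.theta_s,
        Se=se,
    )
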