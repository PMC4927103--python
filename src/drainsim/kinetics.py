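"""Nitrification/denitrification rate laws and their dependency functions.

The sequential mineral-nitrogen chain NH4+ -> NO3- -> N2 is driven by
Michaelis-Menten rate laws whose maximum rates are modulated by

* a water-content (water-filled pore space) dependency, ``fsw`` -- the
  DRAINMOD-N2 three-branch form for nitrification (an aerobic process shut
  off near saturation) and a threshold power law for denitrification (an
  anoxic process that switches on as pores fill);
* a temperature dependency ``ft`` peaking at an optimum temperature;
* for denitrification, an exponential carbon-availability decay with depth
  below the infiltrative surface, ``fz``.

All dependency factors lie in [0, 1].  Saturation ``S`` fed to the water
functions is WFPS = theta/theta_s.  Rates are mg N per litre of pore water
per day.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "NitrificationParams",
    "DenitrificationParams",
    "fsw_nitrification",
    "fsw_denitrification",
    "f_temperature",
    "f_carbon_depth",
    "nitrification_rate",
    "denitrification_rate",
    "speciate_influent",
    "InfluentSpeciation",
    "mu_max_from_effective_rate",
]

# Fitted water-dependency parameters shared by the three mesocosm systems
# (median values that best reproduced the observed chemistry).
_FITTED = dict(fs=0.0, fwp=0.0, swp=0.154, sl=0.665, sh=0.809, e1=2.267, e2=1.104)


@dataclass(frozen=True)
class NitrificationParams:
    """Maximum rate, half-saturation and dependency-function shape.

    ``mu_max`` is mg N L^-1 d^-1 (pore-water basis), ``Km`` mg N L^-1.
    ``fs``/``fwp`` are the fsw values at saturation and wilting point;
    ``swp < sl < sh`` are the saturation breakpoints; ``e1``/``e2`` the
    branch exponents.  ``Topt`` (deg C) and ``beta`` shape the temperature
    response.
    """

    mu_max: float = 50.0
    Km: float = 5.0
    fs: float = _FITTED["fs"]
    fwp: float = _FITTED["fwp"]
    swp: float = _FITTED["swp"]
    sl: float = _FITTED["sl"]
    sh: float = _FITTED["sh"]
    e1: float = _FITTED["e1"]
    e2: float = _FITTED["e2"]
    Topt: float = 22.5
    beta: float = 0.177

    def __post_init__(self) -> None:
        if not (0.0 <= self.fs <= 1.0 and 0.0 <= self.fwp <= 1.0):
            raise ValueError("fs and fwp must lie in [0, 1]")
        if not (0.0 <= self.swp < self.sl < self.sh <= 1.0):
            raise ValueError("require 0 <= swp < sl < sh <= 1")
        if self.mu_max < 0.0 or self.Km <= 0.0:
            raise ValueError("mu_max must be >= 0 and Km > 0")
        if self.Topt <= 0.0:
            raise ValueError("Topt must be positive")


@dataclass(frozen=True)
class DenitrificationParams:
    """Denitrification kinetics: threshold power-law fsw, carbon decay fz."""

    mu_max: float = 5.0
    Km: float = 5.0
    sdn: float = 0.0     # threshold saturation
    f_exp: float = 2.86  # fitted exponent
    alpha_c: float = 0.02  # carbon depth-decay, 1/cm
    Topt: float = 22.5
    beta: float = 0.177

    def __post_init__(self) -> None:
        if not (0.0 <= self.sdn <= 1.0):
            raise ValueError("sdn must lie in [0, 1]")
        if self.f_exp <= 0.0:
            raise ValueError("f_exp must be > 0")
        if self.alpha_c < 0.0:
            raise ValueError("alpha_c must be >= 0")
        if self.mu_max < 0.0 or self.Km <= 0.0:
            raise ValueError("mu_max must be >= 0 and Km > 0")


def _check_saturation(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if np.any(S < 0.0) or np.any(S > 1.0):
        raise ValueError("saturation S must lie in [0, 1]")
    return S


def fsw_nitrification(S, p: NitrificationParams):
    """Three-branch water-content dependency for nitrification.

    ``fwp`` at/below the wilting-point saturation ``swp``, rising as a power
    law to 1 at ``sl``, optimal (1) on (sl, sh], and falling as a power law
    to ``fs`` at full saturation.  Continuous at both breakpoints.
    """
    S = _check_saturation(S)
    out = np.full(S.shape, p.fwp, dtype=float)

    lo = (S > p.swp) & (S <= p.sl)
    out[lo] = p.fwp + (1.0 - p.fwp) * ((S[lo] - p.swp) / (p.sl - p.swp)) ** p.e2

    mid = (S > p.sl) & (S <= p.sh)
    out[mid] = 1.0

    hi = S > p.sh
    out[hi] = p.fs + (1.0 - p.fs) * ((1.0 - S[hi]) / (1.0 - p.sh)) ** p.e1

    return out if out.ndim else float(out)


def fsw_denitrification(S, p: DenitrificationParams):
    """((S - sdn)/(1 - sdn))^f above the threshold ``sdn``, else 0."""
    S = _check_saturation(S)
    if p.sdn >= 1.0:
        out = np.where(S >= 1.0, 1.0, 0.0)
    else:
        base = np.clip((S - p.sdn) / (1.0 - p.sdn), 0.0, 1.0)
        out = base**p.f_exp
    return out if out.ndim else float(out)


def f_temperature(T, Topt: float, beta: float):
    """exp[-0.5 beta Topt + beta T (1 - 0.5 T/Topt)]; equals 1 at T = Topt.

    The exponent is a downward parabola in T with its maximum (0) at Topt,
    so ft <= 1 everywhere and ft(T) = ft(2 Topt - T) by symmetry.
    """
    if Topt <= 0.0:
        raise ValueError("Topt must be positive")
    T = np.asarray(T, dtype=float)
    ft = np.exp(-0.5 * beta * Topt + beta * T * (1.0 - 0.5 * T / Topt))
    return ft if ft.ndim else float(ft)


def f_carbon_depth(z, alpha_c: float):
    """exp(-alpha_c z): organic-carbon availability decays with depth ``z``
    (cm below the infiltrative surface)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0.0):
        raise ValueError("depth z must be >= 0")
    fz = np.exp(-alpha_c * z)
    return fz if fz.ndim else float(fz)


def _mm(C, Km: float):
    C = np.asarray(C, dtype=float)
    if np.any(C < 0.0):
        raise ValueError("concentration must be >= 0")
    return C / (Km + C)


def nitrification_rate(C_NH4, S, T, p: NitrificationParams):
    """mu_nit = mu_max * C/(Km + C) * ft * fsw  (mg N L^-1 d^-1)."""
    r = (
        p.mu_max
        * _mm(C_NH4, p.Km)
        * f_temperature(T, p.Topt, p.beta)
        * fsw_nitrification(S, p)
    )
    return r if np.ndim(r) else float(r)


def denitrification_rate(C_NO3, S, T, z, p: DenitrificationParams):
    """mu_denit = mu_max * C/(Km + C) * ft * fsw_dn * fz  (mg N L^-1 d^-1)."""
    r = (
        p.mu_max
        * _mm(C_NO3, p.Km)
        * f_temperature(T, p.Topt, p.beta)
        * fsw_denitrification(S, p)
        * f_carbon_depth(z, p.alpha_c)
    )
    return r if np.ndim(r) else float(r)


class InfluentSpeciation(NamedTuple):
    nh4: float
    no3: float
    org: float  # recalcitrant organic N passing through untransformed


# ATE: 18% organic N, 26% NH4+, 56% NO3-; the organic fraction is
# mineralized into the NH4+ pool before dosing.  STE: organic N + NH4+,
# fully mineralized to NH4+.
_ATE_NO3_FRACTION = 0.56


def speciate_influent(
    TN: float, source: str, recalcitrant_fraction: float = 0.0
) -> InfluentSpeciation:
    """Split influent total N into dosed NH4+/NO3- concentrations.

    STE -> (TN, 0): organic N is assumed fully mineralized to NH4+ at the
    inlet.  ATE -> (0.44 TN, 0.56 TN): the 18% organic fraction joins the
    26% NH4+ pool.  A nonzero ``recalcitrant_fraction`` diverts that share
    of the *organic* influent N into an inert pool that passes through
    untransformed.
    """
    if TN < 0.0:
        raise ValueError("TN must be >= 0")
    if not (0.0 <= recalcitrant_fraction <= 1.0):
        raise ValueError("recalcitrant_fraction must lie in [0, 1]")
    src = source.upper().replace("&", "")
    if src == "STE":
        org_share = 0.2  # midpoint of the 10-30% organic share in STE
        inert = recalcitrant_fraction * org_share * TN
        return InfluentSpeciation(nh4=TN - inert, no3=0.0, org=inert)
    if src == "ATE":
        inert = recalcitrant_fraction * 0.18 * TN
        nh4 = (1.0 - _ATE_NO3_FRACTION) * TN - inert
        return InfluentSpeciation(nh4=nh4, no3=_ATE_NO3_FRACTION * TN, org=inert)
    raise ValueError(f"unknown effluent source {source!r} (expected STE or ATE)")


def mu_max_from_effective_rate(
    rate: float,
    S: float,
    T: float,
    params,
    z: float = 0.0,
    C_ref: float = np.inf,
):
    """Back out mu_max so the realized rate at a reference state equals ``rate``.

    Given a target effective zero-order rate (mg N L^-1 d^-1) at saturation
    ``S``, temperature ``T`` and (for denitrification) depth ``z``, with the
    substrate far above Km by default (``C_ref = inf``), returns a copy of
    ``params`` whose ``mu_max`` yields exactly that rate at the reference
    state.
    """
    if isinstance(params, NitrificationParams):
        fac = f_temperature(T, params.Topt, params.beta) * fsw_nitrification(S, params)
    elif isinstance(params, DenitrificationParams):
        fac = (
            f_temperature(T, params.Topt, params.beta)
            * fsw_denitrification(S, params)
            * f_carbon_depth(z, params.alpha_c)
        )
    else:
        raise TypeError("params must be Nitrification/DenitrificationParams")
    if np.isfinite(C_ref):
        fac *= _mm(C_ref, params.Km)
    if fac <= 0.0:
        raise ValueError(
            "dependency factors vanish at the reference state; mu_max undefined"
        )
    return replace(params, mu_max=rate / fac)
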