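"""Default parameterization of the three drainfield mesocosm systems.

The hydraulic parameter sets are the calibrated means (n = 3 replicate
mesocosms) from the study the package models; the effective zero-order
nitrification/denitrification rates are the corresponding layer averages.
Systems:

* ``PSND`` -- pressurized shallow narrow drainfield, ATE-dosed, infiltrative
  surface 20 cm below ground under an impermeable half-pipe cover;
* ``GEO``  -- Geomat variant with a 1-cm entangled-filament distribution
  layer and a 2.54-cm pressure pipe, infiltrative surface 25 cm;
* ``P&S``  -- conventional pipe-and-stone trench, STE-dosed, 30-cm crushed
  stone layer with the pipe 60 cm below ground, infiltrative surface 84 cm.

Units package-wide: cm, days, mg N/L, deg C.
"""

from __future__ import annotations

from .hydraulics import VanGenuchtenParams

SYSTEMS = ("PSND", "GEO", "P&S")


def canonical_system(name: str) -> str:
    key = name.upper().replace(" ", "").replace("&", "").replace("_", "")
    table = {"PSND": "PSND", "GEO": "GEO", "GEOMAT": "GEO", "PS": "P&S", "PANDS": "P&S"}
    if key not in table:
        raise ValueError(f"unknown system type {name!r}; expected one of {SYSTEMS}")
    return table[key]


# --- calibrated van Genuchten parameters (means, n=3) ----------------------

SILT_LOAM = {
    "PSND": VanGenuchtenParams(theta_r=0.025, theta_s=0.203, alpha=0.0847, n=2.289, Ks=220.02),
    "GEO": VanGenuchtenParams(theta_r=0.024, theta_s=0.181, alpha=0.0182, n=2.282, Ks=252.43),
}

GRAVELLY_SAND = {
    "PSND": VanGenuchtenParams(theta_r=0.013, theta_s=0.063, alpha=0.0205, n=4.037, Ks=908.88),
    "GEO": VanGenuchtenParams(theta_r=0.014, theta_s=0.138, alpha=0.0189, n=4.282, Ks=942.48),
    "P&S": VanGenuchtenParams(theta_r=0.012, theta_s=0.068, alpha=0.0838, n=3.731, Ks=4.513),
}

# Entangled plastic filaments (GEO) and crushed stone (P&S): highly
# conductive (Ks = 3000 cm/d), coarse-gravel-like retention; excluded from
# calibration.
COARSE_FILL = VanGenuchtenParams(theta_r=0.005, theta_s=0.42, alpha=0.145, n=2.68, Ks=3000.0)

# Uncalibrated silt loam used only above the P&S trench (no flow there).
SILT_LOAM_GENERIC = VanGenuchtenParams(theta_r=0.067, theta_s=0.45, alpha=0.02, n=1.41, Ks=10.8)

# --- bulk density (g/cm^3) and transport ----------------------------------

RHO_B = {"silt_loam": 1.40, "gravelly_sand": 1.60, "coarse_fill": 1.50}

# free-water diffusion, cm^2/h (converted to cm^2/d at the unit boundary)
D_FREE_CM2_PER_H = {"NH4": 0.067, "NO3": 0.061}

# --- geometry (cm) ---------------------------------------------------------

DOMAIN_WIDTH = 15.0
DOMAIN_HEIGHT = 137.0
MESOCOSM_AREA_CM2 = 176.715  # pi * (15/2)^2, converts dose volumes to fluxes

INFILTRATIVE_DEPTH = {"PSND": 20.0, "GEO": 25.0, "P&S": 84.0}
SILT_SAND_INTERFACE = 45.0  # silt-loam / gravelly-sand horizon boundary, cm bgs
STONE_TOP, STONE_BOTTOM = 54.0, 84.0  # P&S crushed-stone trench
PIPE_DEPTH = {"GEO": 23.5, "P&S": 60.0}
PIPE_DIAMETER = 2.54
FILAMENT_THICKNESS = 1.0

# published node counts the auto-generated meshes approximate
REFERENCE_NODE_COUNT = {"PSND": 614, "GEO": 537, "P&S": 478}

OBSERVATION_DEPTHS_BELOW_IS = (15.0, 30.0)

# --- dosing ----------------------------------------------------------------

DOSING = {
    # (dose volume cm^3, dose duration d, period d, source)
    "PSND": dict(volume=42.0, duration=15.0 / 1440.0, period=30.0 / 1440.0, source="ATE"),
    "GEO": dict(volume=42.0, duration=15.0 / 1440.0, period=30.0 / 1440.0, source="ATE"),
    "P&S": dict(volume=200.0, duration=1.5 / 24.0, period=12.0 / 24.0, source="STE"),
}

# --- influent totals (mg N/L); the study's raw chemistry is unpublished,
# so these are literature-typical values for septic-tank effluent and
# sand-filter (advanced-treated) effluent ----------------------------------

INFLUENT_TN = {"STE": dict(mean=60.0, sd=10.0), "ATE": dict(mean=40.0, sd=8.0)}

# --- modeled layer-average WFPS (theta/theta_s), means +/- SD (n=3) --------

WFPS_REFERENCE = {
    "PSND": {"silt_loam": (0.64, 0.06), "gravelly_sand": (0.41, 0.05)},
    "GEO": {"silt_loam": (0.74, 0.15), "gravelly_sand": (0.56, 0.15)},
    "P&S": {"gravelly_sand": (0.27, 0.02)},
}

# --- effective zero-order rates, mg N L^-1 d^-1 (means, n=3) ---------------

NITRIFICATION_RATES = {
    "PSND": {"silt_loam": 45.25, "gravelly_sand": 49.19},
    "GEO": {"silt_loam": 2.17, "gravelly_sand": 24.46, "coarse_fill": 25.88},
    "P&S": {"gravelly_sand": 3.83, "coarse_fill": 12.10},
}

DENITRIFICATION_RATES = {
    "PSND": {"silt_loam": 0.17, "gravelly_sand": 1.31},
    "GEO": {"silt_loam": 0.04, "gravelly_sand": 0.31, "coarse_fill": 0.01},
    "P&S": {"gravelly_sand": 0.36, "coarse_fill": 0.44},
}

# --- reported 90-day N mass-balance fractions (% of N input) ---------------

N_LOSS_REFERENCE = {
    "PSND": {"N2": 10.44},
    "GEO": {"N2": 9.65},
    "P&S": {"N2": 17.60, "NO3": 82.72, "NH4": 1.41},
}


def dispersivity_L(system: str) -> float:
    """Longitudinal dispersivity: one-tenth of the soil profile depth below
    the infiltrative surface."""
    sys = canonical_system(system)
    return 0.1 * (DOMAIN_HEIGHT - INFILTRATIVE_DEPTH[sys])
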