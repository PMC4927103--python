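"""Synthetic mesocosm observations and influent series with known truth.

The generator emulates the structure of the mesocosm experiments: weekly
influent total-N chemistry with source-dependent speciation, sub-daily
moisture probes 15 and 30 cm below the infiltrative surface, and weekly
effluent NH4+/NO3- samples.  Noise is Gaussian additive on moisture and
lognormal multiplicative on concentrations (keeping them non-negative).
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets
from .calibrate import ObservationSet, SteadyProfileModel
from .flow import DosingSchedule, solve_flow
from .geometry import FlowConfig, build_mesocosm
from .hydraulics import VanGenuchtenParams
from .kinetics import speciate_influent
from .transport import InfluentSeries, solve_transport

__all__ = ["SyntheticTruth", "generate_influent_series", "generate_mesocosm_observations"]


def _default_hydraulics(system: str) -> dict[str, VanGenuchtenParams]:
    sysname = presets.canonical_system(system)
    out = {}
    if sysname in presets.SILT_LOAM:
        out["silt_loam"] = presets.SILT_LOAM[sysname]
    out["gravelly_sand"] = presets.GRAVELLY_SAND[sysname]
    return out


@dataclass
class SyntheticTruth:
    """Ground-truth parameter set + noise model for one synthetic mesocosm."""

    system: str = "PSND"
    hydraulics: dict[str, VanGenuchtenParams] = field(default_factory=dict)
    influent_mean: float | None = None  # mg N/L; default per source type
    influent_sd: float | None = None
    moisture_sd: float = 0.005          # cm^3 cm^-3, additive
    conc_cv: float = 0.10               # lognormal CV on concentrations
    seed: int = 0

    def __post_init__(self) -> None:
        self.system = presets.canonical_system(self.system)
        if not self.hydraulics:
            self.hydraulics = _default_hydraulics(self.system)
        src = presets.DOSING[self.system]["source"]
        stats = presets.INFLUENT_TN[src]
        if self.influent_mean is None:
            self.influent_mean = stats["mean"]
        if self.influent_sd is None:
            self.influent_sd = stats["sd"]
        if self.influent_sd < 0 or self.moisture_sd < 0 or self.conc_cv < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def source(self) -> str:
        return presets.DOSING[self.system]["source"]


def generate_influent_series(
    mean: float,
    sd: float,
    n_weeks: int,
    source: str = "STE",
    seed: int = 0,
    recalcitrant_fraction: float = 0.0,
) -> pd.DataFrame:
    """Weekly influent TN draws (Gaussian, truncated at 0), speciated into
    NH4+/NO3- per the source type.  Deterministic given the seed."""
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    tn = np.maximum(mean + sd * rng.standard_normal(n_weeks), 0.0)
    spec = [speciate_influent(v, source, recalcitrant_fraction) for v in tn]
    return pd.DataFrame(
        dict(
            time_d=7.0 * np.arange(n_weeks),
            TN=tn,
            NH4=[s.nh4 for s in spec],
            NO3=[s.no3 for s in spec],
            org=[s.org for s in spec],
        )
    )


def _steady_moisture(truth: SyntheticTruth, depths_bgs: np.ndarray) -> np.ndarray:
    sysname = truth.system
    is_depth = presets.INFILTRATIVE_DEPTH[sysname]
    iface = presets.SILT_SAND_INTERFACE
    layers = []
    if "silt_loam" in truth.hydraulics:
        layers.append((0.0, iface, truth.hydraulics["silt_loam"], "s"))
        layers.append((iface, presets.DOMAIN_HEIGHT, truth.hydraulics["gravelly_sand"], "g"))
    else:
        layers.append((is_depth, presets.DOMAIN_HEIGHT, truth.hydraulics["gravelly_sand"], "g"))
    d = presets.DOSING[sysname]
    q = d["volume"] / d["period"] / presets.MESOCOSM_AREA_CM2
    model = SteadyProfileModel(
        layers, q=q, wt_depth=presets.DOMAIN_HEIGHT - 0.5, obs_depths=depths_bgs
    )
    return model()


def generate_mesocosm_observations(
    truth: SyntheticTruth,
    system_type: str | None = None,
    fidelity: str = "full2d",
    t_end: float = 90.0,
    moisture_per_day: int = 4,
) -> ObservationSet:
    """Run the forward model at the truth and sample it like the mesocosm
    instrumentation: sub-daily moisture at 15/30 cm below the infiltrative
    surface and (for ``fidelity='full2d'``) weekly effluent NH4+/NO3-.

    ``fidelity='steady'`` uses the steady 1D profile (moisture only) and is
    orders of magnitude faster; it is the natural choice for
    parameter-recovery experiments.
    """
    system = presets.canonical_system(system_type or truth.system)
    rng = np.random.default_rng(truth.seed)
    depths = np.array(presets.OBSERVATION_DEPTHS_BELOW_IS)
    depths_bgs = presets.INFILTRATIVE_DEPTH[system] + depths
    t_moist = np.arange(0.0, t_end, 1.0 / moisture_per_day) + 1.0 / moisture_per_day
    rows = []

    if fidelity == "steady":
        theta = _steady_moisture(truth, depths_bgs)
        for d, th in zip(depths, theta):
            noise = truth.moisture_sd * rng.standard_normal(len(t_moist))
            for t, v in zip(t_moist, th + noise):
                rows.append(
                    dict(group=f"moisture@{d:g}cm", time_d=t, value=max(v, 0.0),
                         sigma=max(truth.moisture_sd, 1e-6))
                )
        return ObservationSet(pd.DataFrame(rows))

    if fidelity != "full2d":
        raise ValueError("fidelity must be 'steady' or 'full2d'")

    domain = build_mesocosm(system)
    domain.materials = [
        replace(m, vg=truth.hydraulics.get(m.name, m.vg)) for m in domain.materials
    ]
    cfg = FlowConfig(t_end=t_end)
    schedule = DosingSchedule.for_system(system)
    fres = solve_flow(domain, schedule, cfg)

    n_weeks = int(np.ceil(t_end / 7.0))
    infl = generate_influent_series(
        truth.influent_mean, truth.influent_sd, n_weeks, truth.source,
        seed=truth.seed + 1,
    )
    series = InfluentSeries.from_tn(infl["time_d"], infl["TN"], truth.source)
    tres = solve_transport(fres, series)

    probes = [n for n in domain.observation_nodes if n.name.startswith("probe")]
    for node, d in zip(probes, depths):
        th = np.interp(t_moist, fres.times, fres.theta[:, node.iz, node.ix])
        noise = truth.moisture_sd * rng.standard_normal(len(t_moist))
        for t, v in zip(t_moist, th + noise):
            rows.append(
                dict(group=f"moisture@{d:g}cm", time_d=t, value=max(v, 0.0),
                     sigma=max(truth.moisture_sd, 1e-6))
            )

    eff = tres.effluent
    t_week = np.arange(7.0, t_end + 1e-9, 7.0)
    for sp in ("NH4", "NO3"):
        c = np.interp(t_week, eff["time_d"], eff[f"C_{sp}"])
        if truth.conc_cv > 0:
            s2 = np.log(1.0 + truth.conc_cv**2)
            noise = rng.standard_normal(len(t_week))
            c = c * np.exp(np.sqrt(s2) * noise - 0.5 * s2)
        sigma = np.maximum(truth.conc_cv * max(np.mean(c), 1e-6), 1e-6)
        for t, v in zip(t_week, c):
            rows.append(
                dict(group=f"effluent {sp}", time_d=t, value=v, sigma=sigma)
            )
    return ObservationSet(pd.DataFrame(rows))
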