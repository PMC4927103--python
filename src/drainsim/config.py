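"""YAML run-configuration schema, validation and the run pipeline.

A run configuration names a system, optionally overrides geometry,
materials (hydraulics + transport + kinetics blocks), boundaries, dosing
and run controls, and is validated strictly (unknown keys rejected,
physical invariants enforced at the boundary).  ``run_pipeline`` executes
the requested stages, writes CSV/VTK/JSON outputs and a manifest with the
configuration hash so reruns are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import presets
from .flow import DosingSchedule, solve_flow, water_balance, wfps_by_layer, point_series
from .geometry import FlowConfig, build_mesocosm, write_vtk
from .hydraulics import VanGenuchtenParams
from .kinetics import DenitrificationParams, NitrificationParams
from .scenarios import SCENARIOS, apply_scenario
from .transport import InfluentSeries, nitrogen_mass_balance, solve_transport

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VGBlock(_Strict):
    theta_r: float
    theta_s: float
    alpha: float
    n: float
    Ks: float
    l: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        VanGenuchtenParams(**self.model_dump())  # raises on invalid sets
        return self

    def build(self) -> VanGenuchtenParams:
        return VanGenuchtenParams(**self.model_dump())


class TransportBlock(_Strict):
    rho_b: float = 1.5
    lambda_L: Optional[float] = None  # default: 0.1 x profile below the IS
    lambda_T: Optional[float] = None  # default: lambda_L / 10
    Kd: float = 0.0


class KineticsBlock(_Strict):
    nitrification: Optional[dict] = None    # NitrificationParams fields
    denitrification: Optional[dict] = None  # DenitrificationParams fields

    @model_validator(mode="after")
    def _check(self):
        if self.nitrification is not None:
            NitrificationParams(**self.nitrification)
        if self.denitrification is not None:
            DenitrificationParams(**self.denitrification)
        return self


class MaterialBlock(_Strict):
    name: str
    z_top: float
    z_bottom: float
    vg: VGBlock
    transport: TransportBlock = Field(default_factory=TransportBlock)
    kinetics: Optional[KineticsBlock] = None
    native: bool = True

    @model_validator(mode="after")
    def _check(self):
        if not self.z_top < self.z_bottom:
            raise ValueError(f"material {self.name}: require z_top < z_bottom")
        return self


class GeometryBlock(_Strict):
    width: float = presets.DOMAIN_WIDTH
    height: float = presets.DOMAIN_HEIGHT
    infiltrative_depth: Optional[float] = None
    dz_fine: float = 0.42
    dz_max: float = 3.5


class BoundariesBlock(_Strict):
    seepage_pool_height: float = 0.0
    flux_width: Optional[float] = None


class DosingBlock(_Strict):
    volume: float
    duration: float
    period: float
    source: Literal["STE", "ATE"]
    resolve_pulses: Optional[bool] = None

    def build(self) -> DosingSchedule:
        return DosingSchedule(**self.model_dump())


class RunBlock(_Strict):
    t_end: float = 90.0
    temperature: float = 20.0
    h_init: float = -50.0
    h_crit_min: float = -1000.0
    seed: int = 0
    scenario: Optional[str] = None  # baseline / 23c / iwt / iwt+23c


class InfluentBlock(_Strict):
    TN_mean: Optional[float] = None  # default per source type
    TN_sd: float = 0.0
    recalcitrant_fraction: float = 0.0


class RunConfig(_Strict):
    system: Literal["PSND", "GEO", "P&S"]
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    materials: Optional[list[MaterialBlock]] = None  # None -> system defaults
    boundaries: BoundariesBlock = Field(default_factory=BoundariesBlock)
    dosing: Optional[DosingBlock] = None             # None -> system default
    influent: InfluentBlock = Field(default_factory=InfluentBlock)
    run: RunBlock = Field(default_factory=RunBlock)
    observation_depths_cm: list[float] = Field(
        default_factory=lambda: list(presets.OBSERVATION_DEPTHS_BELOW_IS)
    )


def load_config(path) -> RunConfig:
    """Load + schema-validate a YAML run configuration; defaults injected,
    unknown keys rejected with the offending key named."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(json.loads(cfg.model_dump_json()), f, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """sha256 over the canonical JSON form: changes iff a semantically
    meaningful field changes."""
    canon = json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------


def _domain_from(cfg: RunConfig):
    ov: dict = dict(
        width=cfg.geometry.width,
        height=cfg.geometry.height,
        dz_fine=cfg.geometry.dz_fine,
        dz_max=cfg.geometry.dz_max,
        flux_width=cfg.boundaries.flux_width,
    )
    if cfg.geometry.infiltrative_depth is not None:
        ov["infiltrative_depth"] = cfg.geometry.infiltrative_depth
    if cfg.materials is not None:
        from .geometry import MaterialZone

        lamL_default = presets.dispersivity_L(cfg.system)
        mats = []
        for mb in cfg.materials:
            lamL = mb.transport.lambda_L or lamL_default
            lamT = mb.transport.lambda_T or lamL / 10.0
            nit = den = None
            if mb.kinetics is not None:
                if mb.kinetics.nitrification is not None:
                    nit = NitrificationParams(**mb.kinetics.nitrification)
                if mb.kinetics.denitrification is not None:
                    den = DenitrificationParams(**mb.kinetics.denitrification)
            mats.append(
                (
                    mb.z_top,
                    mb.z_bottom,
                    MaterialZone(
                        name=mb.name, vg=mb.vg.build(), rho_b=mb.transport.rho_b,
                        lambda_L=lamL, lambda_T=lamT, Kd=mb.transport.Kd,
                        nit=nit, denit=den, native=mb.native,
                    ),
                )
            )
        ov["materials"] = mats
    return build_mesocosm(cfg.system, ov)


def _flow_config_from(cfg: RunConfig) -> FlowConfig:
    fc = FlowConfig(
        h_init=cfg.run.h_init,
        h_crit_min=cfg.run.h_crit_min,
        t_end=cfg.run.t_end,
        temperature=cfg.run.temperature,
        seepage_pool_height=cfg.boundaries.seepage_pool_height,
    )
    if cfg.run.scenario:
        key = cfg.run.scenario.lower()
        if key not in SCENARIOS:
            raise ValueError(f"unknown scenario {cfg.run.scenario!r}")
        fc = apply_scenario(fc, SCENARIOS[key])
    return fc


STAGES = ("flow", "transport")


def run_pipeline(cfg: RunConfig, stages=("flow",), out_dir="run", log=print) -> Path:
    """Execute the requested stages and write a self-describing run
    directory (CSV series, VTK snapshot, JSON reports, manifest)."""
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "transport" in stages and "flow" not in stages:
        raise ValueError("stage dependency: transport requires flow")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    domain = _domain_from(cfg)
    fc = _flow_config_from(cfg)
    schedule = cfg.dosing.build() if cfg.dosing else DosingSchedule.for_system(cfg.system)

    fres = None
    if "flow" in stages:
        fres = solve_flow(domain, schedule, fc)
        wb = water_balance(fres)
        log(f"[flow] {len(fres.times)} steps, water-balance error {wb['relative_error']:.2e}")
        for node in domain.observation_nodes:
            if node.name.startswith("probe"):
                df = point_series(fres, node.name)
                f = out / f"flow_{node.name}.csv"
                df.to_csv(f, index=False, float_format="%.8g")
                outputs.append(f.name)
        wfps = wfps_by_layer(fres)
        (out / "flow_summary.json").write_text(
            json.dumps(dict(water_balance=wb, wfps_by_layer=wfps), indent=2, default=float)
        )
        outputs.append("flow_summary.json")
        write_vtk(domain, str(out / "fields_final.vtk"),
                  dict(theta=fres.theta[-1], head=fres.h[-1]))
        outputs.append("fields_final.vtk")

    if "transport" in stages:
        src = schedule.source
        tn = cfg.influent.TN_mean or presets.INFLUENT_TN[src]["mean"]
        if cfg.influent.TN_sd > 0:
            from .synthetic import generate_influent_series

            infl = generate_influent_series(
                tn, cfg.influent.TN_sd, int(cfg.run.t_end // 7) + 1, src,
                seed=cfg.run.seed, recalcitrant_fraction=cfg.influent.recalcitrant_fraction,
            )
            series = InfluentSeries.from_tn(
                infl["time_d"], infl["TN"], src, cfg.influent.recalcitrant_fraction
            )
        else:
            series = InfluentSeries.constant(tn, src, cfg.influent.recalcitrant_fraction)
        tres = solve_transport(fres, series, temperature=fc.temperature)
        mb = nitrogen_mass_balance(tres)
        log(f"[transport] N closure error {mb.closure_error_pct:.3f}% of input")
        tres.effluent.to_csv(out / "effluent.csv", index=False, float_format="%.8g")
        outputs.append("effluent.csv")
        (out / "mass_balance.json").write_text(json.dumps(mb.as_dict(), indent=2, default=float))
        outputs.append("mass_balance.json")

    manifest = dict(
        package="drainsim",
        version=__import__("drainsim").__version__,
        config_hash=config_hash(cfg),
        seed=cfg.run.seed,
        stages=stages,
        created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    dump_config(cfg, out / "config.yaml")
    return out
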