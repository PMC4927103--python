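"""Climate scenarios: warmer soil, raised water table, and their combination.

The baseline run is 20 deg C with the seepage face at the column bottom.
Scenario (i) raises the constant soil temperature to 23 deg C; scenario
(ii) raises the hanging water table 30 cm (the seepage face maintains a
pool 30 cm above the bottom, shrinking the unsaturated zone accordingly);
scenario (iii) applies both.  Scenario application is a pure transformation
of the run configuration -- baselines are never mutated -- and "both" is
the sequential composition of (i) and (ii), order-independent by
construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from . import presets
from .flow import DosingSchedule, FlowResult, solve_flow
from .geometry import Domain, FlowConfig, GeometryError, ObservationNode, build_mesocosm
from .transport import (
    InfluentSeries,
    NMassBalance,
    TransportResult,
    nitrogen_mass_balance,
    solve_transport,
)

__all__ = [
    "Scenario",
    "BASELINE",
    "WARMER",
    "RAISED_WT",
    "COMBINED",
    "apply_scenario",
    "run_scenario",
    "ScenarioRun",
    "compare_runs",
]


@dataclass(frozen=True)
class Scenario:
    temperature: float = 20.0
    water_table_rise: float = 0.0
    label: str = "baseline"

    def __post_init__(self) -> None:
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive (deg C)")
        if self.water_table_rise < 0.0:
            raise ValueError("water_table_rise must be >= 0")


BASELINE = Scenario()
WARMER = Scenario(temperature=23.0, label="23C")
RAISED_WT = Scenario(water_table_rise=30.0, label="IWT")
COMBINED = Scenario(temperature=23.0, water_table_rise=30.0, label="IWT+23C")

SCENARIOS = {s.label.lower(): s for s in (BASELINE, WARMER, RAISED_WT, COMBINED)}


def apply_scenario(cfg: FlowConfig, scenario: Scenario, domain: Domain | None = None) -> FlowConfig:
    """Return a new FlowConfig with the scenario applied (pure; ``cfg`` is
    untouched).  Raises GeometryError if the rise consumes the whole
    unsaturated zone below the infiltrative surface."""
    if domain is not None:
        unsat = domain.height - domain.infiltrative_depth
        if scenario.water_table_rise >= unsat:
            raise GeometryError(
                f"water-table rise {scenario.water_table_rise} cm >= unsaturated "
                f"thickness {unsat} cm below the infiltrative surface"
            )
    return dataclasses.replace(
        cfg,
        temperature=scenario.temperature,
        seepage_pool_height=cfg.seepage_pool_height + scenario.water_table_rise,
    )


def _add_water_table_node(domain: Domain, pool_height: float) -> None:
    if pool_height <= 0.0:
        return
    z = domain.height - pool_height
    iz, ix = domain.nearest_cell(domain.width / 2.0, z)
    domain.observation_nodes.append(
        ObservationNode("water_table", z, z - domain.infiltrative_depth, iz, ix)
    )


@dataclass
class ScenarioRun:
    """One completed flow+transport run under a scenario."""

    system: str
    scenario: Scenario
    flow: FlowResult
    transport: TransportResult
    mass_balance: NMassBalance

    @property
    def effluent(self) -> pd.DataFrame:
        return self.transport.effluent

    def mean_effluent(self, species: str, window: float = 30.0) -> float:
        """Flux-weighted mean outlet concentration over the final window."""
        eff = self.transport.effluent
        m = eff["time_d"] >= eff["time_d"].iloc[-1] - window
        w = eff.loc[m, "outflow"]
        if w.sum() <= 0:
            return 0.0
        return float((eff.loc[m, f"C_{species}"] * w).sum() / w.sum())


def run_scenario(
    system: str,
    scenario: Scenario = BASELINE,
    t_end: float = 90.0,
    influent: InfluentSeries | None = None,
    base_cfg: FlowConfig | None = None,
) -> ScenarioRun:
    """Build the system domain, apply the scenario, and run flow + reactive
    transport end to end."""
    system = presets.canonical_system(system)
    domain = build_mesocosm(system)
    cfg = apply_scenario(base_cfg or FlowConfig(t_end=t_end), scenario, domain)
    cfg = dataclasses.replace(cfg, t_end=t_end)
    _add_water_table_node(domain, cfg.seepage_pool_height)
    schedule = DosingSchedule.for_system(system)
    if influent is None:
        src = schedule.source
        influent = InfluentSeries.constant(presets.INFLUENT_TN[src]["mean"], src)
    fres = solve_flow(domain, schedule, cfg)
    tres = solve_transport(fres, influent)
    return ScenarioRun(system, scenario, fres, tres, nitrogen_mass_balance(tres))


@dataclass
class DeltaReport:
    baseline_label: str
    scenario_label: str
    d_n2_pct_points: float
    n2_relative_change_pct: float
    d_mean_effluent_nh4: float
    d_mean_effluent_no3: float
    baseline_n2_pct: float
    scenario_n2_pct: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_runs(baseline: ScenarioRun, scenario: ScenarioRun) -> DeltaReport:
    """Scenario-minus-baseline deltas in the N2 loss fraction and in the
    mean effluent concentrations.  Runs must be for the same system."""
    if baseline.system != scenario.system:
        raise ValueError(
            f"cannot compare {baseline.system} baseline with {scenario.system} run"
        )
    b_n2 = baseline.mass_balance.pct_n2
    s_n2 = scenario.mass_balance.pct_n2
    rel = 100.0 * (s_n2 - b_n2) / b_n2 if b_n2 > 0 else float("inf") if s_n2 > 0 else 0.0
    return DeltaReport(
        baseline_label=baseline.scenario.label,
        scenario_label=scenario.scenario.label,
        d_n2_pct_points=s_n2 - b_n2,
        n2_relative_change_pct=rel,
        d_mean_effluent_nh4=scenario.mean_effluent("NH4") - baseline.mean_effluent("NH4"),
        d_mean_effluent_no3=scenario.mean_effluent("NO3") - baseline.mean_effluent("NO3"),
        baseline_n2_pct=b_n2,
        scenario_n2_pct=s_n2,
    )
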