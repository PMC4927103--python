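import numpy as np
import pytest

from drainsim import build_column, build_mesocosm, presets
from drainsim.flow import DosingSchedule, solve_flow
from drainsim.geometry import FlowConfig


def constant_flux_schedule(q_cm_per_day: float, source: str = "ATE") -> DosingSchedule:
    """A degenerate schedule delivering a constant flux (duration == period)."""
    return DosingSchedule(
        volume=q_cm_per_day * presets.MESOCOSM_AREA_CM2,
        duration=1.0,
        period=1.0,
        source=source,
    )


@pytest.fixture(scope="session")
def psnd_flow_90():
    """90-day PSND baseline flow field (shared by several acceptance checks)."""
    domain = build_mesocosm("PSND")
    return solve_flow(domain, DosingSchedule.for_system("PSND"), FlowConfig(t_end=90.0))


@pytest.fixture(scope="session")
def geo_flow_90():
    domain = build_mesocosm("GEO")
    return solve_flow(domain, DosingSchedule.for_system("GEO"), FlowConfig(t_end=90.0))


@pytest.fixture(scope="session")
def ps_flow_90():
    domain = build_mesocosm("P&S")
    return solve_flow(domain, DosingSchedule.for_system("P&S"), FlowConfig(t_end=90.0))


@pytest.fixture(scope="session")
def sand_column_flow():
    """Homogeneous gravelly-sand column under the PSND loading rate, solved
    to steady state: the workhorse for analytic-oracle comparisons.  Tall
    enough (150 cm) that the interior sits far above the capillary fringe
    of the bottom water table."""
    vg = presets.GRAVELLY_SAND["PSND"]
    domain = build_column(vg, height=150.0, nz=150, nx=1)
    q = 2000.0 / presets.MESOCOSM_AREA_CM2
    cfg = FlowConfig(t_end=20.0, h_init=-69.0)
    return domain, q, solve_flow(domain, constant_flux_schedule(q), cfg)
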