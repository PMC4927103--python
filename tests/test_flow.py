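"""Richards flow solver: equilibrium, analytic oracles, conservation and
dosing behaviour (mostly on cheap homogeneous columns)."""

import numpy as np
import pytest

from drainsim import build_column, build_mesocosm, presets, unit_gradient_state
from drainsim.flow import (
    DosingSchedule,
    PondingError,
    point_series,
    solve_flow,
    water_balance,
    wfps_by_layer,
)
from drainsim.geometry import FlowConfig
from drainsim.hydraulics import VanGenuchtenParams

from conftest import constant_flux_schedule

SAND = presets.GRAVELLY_SAND["PSND"]


class TestSchedule:
    def test_invalid_schedules(self):
        with pytest.raises(ValueError):
            DosingSchedule(volume=-1.0, duration=0.1, period=0.5)
        with pytest.raises(ValueError):
            DosingSchedule(volume=10.0, duration=0.6, period=0.5)  # overlap

    def test_smoothing_rule(self):
        assert not DosingSchedule.for_system("PSND").resolved  # 30-min period
        assert DosingSchedule.for_system("P&S").resolved       # 12-h period
        forced = DosingSchedule.for_system("PSND", resolve_pulses=True)
        assert forced.resolved

    def test_flux_values(self):
        s = DosingSchedule.for_system("P&S")
        assert s.daily_volume == pytest.approx(400.0)
        assert s.flux(0.01) == pytest.approx(s.pulse_flux)
        assert s.flux(0.4) == 0.0
        ev = s.event_times(1.0)
        assert len(ev) == 3  # dose end, next start, next end within (0, 1)


class TestHydrostaticEquilibrium:
    def test_stationary_over_ten_days(self):
        """Zero flux + hydrostatic initial state (water table at the bottom)
        must not drift."""
        dom = build_column(SAND, height=100.0, nz=50)
        h0 = (dom.zc - dom.z_edges[-1])[:, None]  # h = z - H, zero at bottom
        res = solve_flow(dom, None, FlowConfig(t_end=10.0), h0=h0)
        drift = np.max(np.abs(res.h[-1] - res.h[0]))
        assert drift < 1e-6

    def test_drainage_balance_with_zero_dosing(self):
        """A column saturated at the bottom above the seepage level drains:
        storage loss equals seepage outflow."""
        dom = build_column(SAND, height=100.0, nz=50)
        h0 = (dom.zc - 80.0)[:, None]  # water table at 80 cm: bottom 20 cm ponded
        res = solve_flow(dom, None, FlowConfig(t_end=2.0), h0=h0)
        wb = water_balance(res)
        assert wb["inflow"] == 0.0
        assert wb["outflow"] > 0.0
        assert wb["delta_storage"] == pytest.approx(-wb["outflow"], rel=1e-6)


class TestUnitGradientOracle:
    def test_interior_state_matches_analytic(self, sand_column_flow):
        dom, q, res = sand_column_flow
        ug = unit_gradient_state(q, SAND)
        iz = int(np.argmin(np.abs(dom.zc - 20.0)))  # interior, above the fringe
        theta = res.theta[-1][iz, 0]
        assert theta == pytest.approx(ug.theta, rel=0.01)

    def test_seepage_discharges_steady_inflow(self, sand_column_flow):
        dom, q, res = sand_column_flow
        expected = q * dom.width
        assert res.seepage_outflow[-1] == pytest.approx(expected, rel=0.005)

    def test_water_balance_closure(self, sand_column_flow):
        _, _, res = sand_column_flow
        assert water_balance(res)["relative_error"] < 0.005


class TestThetaBounds:
    def test_theta_within_physical_range(self, sand_column_flow):
        _, _, res = sand_column_flow
        assert np.all(res.theta >= SAND.theta_r - 1e-9)
        assert np.all(res.theta <= SAND.theta_s + 1e-9)


class TestPulsedDosing:
    @pytest.fixture(scope="class")
    def pulsed_column(self):
        dom = build_column(SAND, height=60.0, nz=60)
        sch = DosingSchedule(volume=200.0, duration=1.5 / 24, period=0.5, source="STE")
        res = solve_flow(dom, sch, FlowConfig(t_end=4.0, dt_max=0.02))
        return dom, sch, res

    def test_moisture_peaks_after_dose_and_decays(self, pulsed_column):
        dom, sch, res = pulsed_column
        iz = int(np.argmin(np.abs(dom.zc - 10.0)))
        th = res.theta[:, iz, 0]
        t = res.times
        cycle = (t >= 3.0) & (t < 3.5)  # one dosing cycle at quasi-periodicity
        t_peak = t[cycle][np.argmax(th[cycle])]
        assert t_peak < 3.25  # peak shortly after the dose (dose ends at 3.0625)
        assert th[cycle].max() > 1.02 * th[cycle].min()
        # decays between the dose end and the next dose
        tail = (t >= 3.2) & (t < 3.5)
        assert th[tail][-1] <= th[tail][0]

    def test_pulse_closure(self, pulsed_column):
        _, _, res = pulsed_column
        assert water_balance(res)["relative_error"] < 0.005


class TestPonding:
    def test_flux_above_ks_raises(self):
        tight = VanGenuchtenParams(0.05, 0.4, 0.02, 1.8, 2.0)  # Ks = 2 cm/d
        dom = build_column(tight, height=30.0, nz=30)
        with pytest.raises(PondingError):
            # 50 cm/d into a 2 cm/d soil: even the saturated column cannot
            # convey it without unbounded pressure build-up
            solve_flow(dom, constant_flux_schedule(50.0), FlowConfig(t_end=5.0))


class TestGridConvergence:
    def test_wfps_stable_under_refinement(self):
        """Halving element size and the step ceiling moves the column-mean
        WFPS by < 2%."""
        q = 2000.0 / presets.MESOCOSM_AREA_CM2
        vals = []
        for nz, dt_max in ((50, 0.5), (100, 0.25)):
            dom = build_column(SAND, height=100.0, nz=nz)
            cfg = FlowConfig(t_end=15.0, dt_max=dt_max)
            res = solve_flow(dom, constant_flux_schedule(q), cfg)
            vals.append(wfps_by_layer(res, method="volume", window=5.0)["soil"])
        assert abs(vals[1] - vals[0]) / vals[0] < 0.02


class TestWfpsSummaries:
    def test_volume_method_excludes_saturated_bottom(self, sand_column_flow):
        dom, q, res = sand_column_flow
        v = wfps_by_layer(res, method="volume", window=5.0)["soil"]
        o = wfps_by_layer(res, method="observation", window=5.0)
        assert 0.0 < v < 1.0
        # the column has probes only if observation nodes were placed
        assert isinstance(o, dict)

    def test_unknown_method(self, sand_column_flow):
        _, _, res = sand_column_flow
        with pytest.raises(ValueError):
            wfps_by_layer(res, method="nonsense")

    def test_point_series_roundtrip(self, psnd_flow_90):
        df = point_series(psnd_flow_90, "probe_15cm")
        assert {"time_d", "h_cm", "theta"} <= set(df.columns)
        assert len(df) == len(psnd_flow_90.times)
        with pytest.raises(KeyError):
            point_series(psnd_flow_90, "probe_99cm")


class TestSeepageBehaviour:
    def test_saturated_zone_persists_above_seepage_node(self, psnd_flow_90):
        """The hanging water table: near-zero pressure heads at the bottom
        of the 90-day PSND run."""
        h_bottom = psnd_flow_90.h[-1][-1, :]
        assert np.all(h_bottom > -1.0)
        assert h_bottom.max() >= 0.0

    def test_outflow_matches_inflow_at_steady_state(self, psnd_flow_90):
        assert psnd_flow_90.seepage_outflow[-1] == pytest.approx(
            psnd_flow_90.inflow_rate[-1], rel=0.005
        )
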