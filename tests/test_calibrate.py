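"""Gauss-Newton weighted least squares, composite scaled sensitivities and
RMSE, exercised with the fast steady-profile forward model."""

import numpy as np
import pandas as pd
import pytest

from drainsim import presets
from drainsim.calibrate import (
    CSS_EXCLUDE_RATIO,
    ObservationSet,
    RankDeficiencyError,
    SteadyProfileModel,
    composite_scaled_sensitivity,
    gauss_newton_fit,
    rmse,
    weighted_sse,
)

Q = 2000.0 / presets.MESOCOSM_AREA_CM2
SILT = presets.SILT_LOAM["PSND"]
SAND = presets.GRAVELLY_SAND["PSND"]


def psnd_layers():
    return [
        (0.0, presets.SILT_SAND_INTERFACE, SILT, "s"),
        (presets.SILT_SAND_INTERFACE, presets.DOMAIN_HEIGHT, SAND, "g"),
    ]


def replicated(model, n_rep):
    """Align a per-depth forward model with replicated observation rows."""
    return lambda p: np.repeat(np.asarray(model(p), float), n_rep)


def moisture_obs(model, params=None, sigma=0.005, n_rep=40, noise=0.0, seed=0):
    """Observation table sampled from the forward model (replicated probe
    readings, optional Gaussian noise); rows align with replicated(model, n_rep)."""
    theta = model(params or {})
    rng = np.random.default_rng(seed)
    rows = []
    for d, th in zip(model.obs_depths, theta):
        for k in range(n_rep):
            rows.append(
                dict(group=f"moisture@{d:g}cm", time_d=float(k),
                     value=th + noise * rng.standard_normal(), sigma=sigma)
            )
    return ObservationSet(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def psnd_model():
    # probe depths 35 and 50 cm bgs (15/30 below the infiltrative surface)
    return SteadyProfileModel(psnd_layers(), q=Q, wt_depth=136.0, obs_depths=[35.0, 50.0])


@pytest.fixture(scope="module")
def deep_model():
    # denser sounding through both layers: identifies more parameters
    depths = [25.0, 30.0, 35.0, 40.0, 50.0, 60.0, 80.0, 100.0]
    return SteadyProfileModel(psnd_layers(), q=Q, wt_depth=136.0, obs_depths=depths)


class TestObjectives:
    def test_weighted_sse_basics(self, psnd_model):
        obs = moisture_obs(psnd_model, n_rep=1)
        assert weighted_sse({}, replicated(psnd_model, 1), obs) == pytest.approx(0.0, abs=1e-20)

    def test_weighted_sse_single_residual(self):
        obs = ObservationSet(pd.DataFrame(
            [dict(group="g", time_d=0.0, value=3.0, sigma=1.0)]
        ))
        assert weighted_sse({}, lambda p: np.array([1.0]), obs) == pytest.approx(4.0)

    def test_weighted_sse_linear_in_weights(self):
        df = pd.DataFrame(
            [dict(group="g", time_d=0.0, value=3.0, sigma=1.0),
             dict(group="g", time_d=1.0, value=1.0, sigma=1.0)]
        )
        model = lambda p: np.array([1.0, 0.0])
        base = weighted_sse({}, model, ObservationSet(df))
        half = df.assign(sigma=df.sigma / np.sqrt(2.0))  # doubles every weight
        assert weighted_sse({}, model, ObservationSet(half)) == pytest.approx(2 * base)

    def test_rmse_identities(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 2.0], [3.0, 4.0]) == pytest.approx(2.0)
        assert rmse([1, -1, 1, -1], [0, 0, 0, 0]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rmse([], [])


class TestGaussNewton:
    def test_linear_model_single_accepted_step(self):
        """On a linear forward model the undamped step lands exactly on the
        optimum: one accepted step."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        truth = np.array([2.0, -1.0])
        obs = ObservationSet(pd.DataFrame(
            [dict(group="g", time_d=i, value=v, sigma=1.0)
             for i, v in enumerate(X @ truth)]
        ))
        model = lambda p: X @ np.array([p["a"], p["b"]])
        res = gauss_newton_fit(model, obs, init=dict(a=0.5, b=0.5))
        assert res.converged
        assert res.n_accepted_steps == 1
        assert res.params["a"] == pytest.approx(2.0)
        assert res.params["b"] == pytest.approx(-1.0)

    def test_noiseless_recovery_within_0p1_percent(self, deep_model):
        truth = {"s.theta_s": 0.203, "s.n": 2.289, "g.theta_s": 0.063}
        obs = moisture_obs(deep_model, truth, n_rep=5)
        init = {"s.theta_s": 0.24, "s.n": 2.0, "g.theta_s": 0.075}
        res = gauss_newton_fit(replicated(deep_model, 5), obs, init, max_iter=30)
        for k, v in truth.items():
            assert res.params[k] == pytest.approx(v, rel=1e-3)
        assert res.objective_history[-1] < 1e-8 * max(res.objective_history[0], 1e-12)

    def test_noisy_recovery_of_theta_ss(self, deep_model):
        """5% multiplicative noise, 3 x 40 replicate readings: theta_ss is
        recovered within a few percent."""
        obs = moisture_obs(deep_model, sigma=0.006, n_rep=120, noise=0.006, seed=11)
        init = {"s.theta_s": 0.24, "s.n": 2.0}
        res = gauss_newton_fit(replicated(deep_model, 120), obs, init, max_iter=20)
        assert res.params["s.theta_s"] == pytest.approx(0.203, rel=0.05)

    def test_ten_parameter_fit_converges(self, deep_model):
        """Simultaneous fit of all five van Genuchten parameters in both
        horizons (10 parameters), as in the mesocosm calibrations."""
        obs = moisture_obs(deep_model, n_rep=3)
        init, bounds = {}, {}
        for tag, vg in (("s", SILT), ("g", SAND)):
            init[f"{tag}.theta_r"] = vg.theta_r * 1.2
            init[f"{tag}.theta_s"] = vg.theta_s * 1.05
            init[f"{tag}.alpha"] = vg.alpha * 0.9
            init[f"{tag}.n"] = vg.n * 0.95
            init[f"{tag}.Ks"] = vg.Ks * 1.2
            bounds[f"{tag}.theta_r"] = (0.001, 0.05)
            bounds[f"{tag}.theta_s"] = (0.055, 0.5)
            bounds[f"{tag}.alpha"] = (0.001, 0.5)
            bounds[f"{tag}.n"] = (1.2, 6.0)
            bounds[f"{tag}.Ks"] = (1.0, 5000.0)
        res = gauss_newton_fit(replicated(deep_model, 3), obs, init, bounds=bounds,
                               max_iter=25, screen_css=True)
        assert res.converged
        assert res.objective_history[-1] < 1e-6 * res.objective_history[0]

    def test_rank_deficiency_named(self, psnd_model):
        obs = moisture_obs(psnd_model, n_rep=2)
        base = replicated(psnd_model, 2)
        model = lambda p: base({k: v for k, v in p.items() if k != "dead"})
        with pytest.raises(RankDeficiencyError) as ei:
            gauss_newton_fit(model, obs, init={"s.theta_s": 0.22, "dead": 1.0})
        assert "dead" in str(ei.value)

    def test_more_parameters_than_observations_rejected(self, psnd_model):
        obs = moisture_obs(psnd_model, n_rep=1)  # 2 observations
        with pytest.raises(ValueError):
            gauss_newton_fit(replicated(psnd_model, 1), obs,
                             init={"s.theta_s": 0.2, "s.n": 2.0, "g.n": 4.0})


class TestCSS:
    def test_inert_parameter_flagged(self, psnd_model):
        base = replicated(psnd_model, 2)
        model = lambda p: base({k: v for k, v in p.items() if k != "inert"})
        obs = moisture_obs(psnd_model, n_rep=2)
        css, ratios, excluded = composite_scaled_sensitivity(
            model, {"s.theta_s": 0.203, "inert": 5.0}, obs
        )
        assert css["inert"] == 0.0
        assert "inert" in excluded
        assert ratios["s.theta_s"] == 1.0

    def test_exclusion_threshold(self):
        assert CSS_EXCLUDE_RATIO == 0.01

    def test_unit_rescaling_invariance(self, psnd_model):
        """Rescaling observation units with weights ~ 1/sigma^2 rescaled
        accordingly leaves CSS unchanged."""
        params = {"s.theta_s": 0.203, "s.n": 2.289}
        obs = moisture_obs(psnd_model, n_rep=2, sigma=0.005)
        base = replicated(psnd_model, 2)
        css1, _, _ = composite_scaled_sensitivity(base, params, obs)
        scaled = ObservationSet(obs.data.assign(
            value=obs.data.value * 1000.0, sigma=obs.data.sigma * 1000.0
        ))
        model_mm = lambda p: base(p) * 1000.0
        css2, _, _ = composite_scaled_sensitivity(model_mm, params, scaled)
        for k in params:
            assert css2[k] == pytest.approx(css1[k], rel=1e-6)

    def test_theta_ss_attains_maximum_css(self, psnd_model):
        """On PSND-like moisture data the silt-loam saturated water content
        dominates the composite scaled sensitivities."""
        params = {}
        for tag, vg in (("s", SILT), ("g", SAND)):
            for f in ("theta_r", "theta_s", "alpha", "n", "Ks"):
                params[f"{tag}.{f}"] = getattr(vg, f)
        obs = moisture_obs(psnd_model, n_rep=3, sigma=0.005)
        css, ratios, _ = composite_scaled_sensitivity(replicated(psnd_model, 3), params, obs)
        top = max(css, key=css.get)
        assert top == "s.theta_s"
        assert ratios["s.theta_s"] == 1.0


class TestSteadyProfileModel:
    def test_observation_below_water_table_rejected(self):
        with pytest.raises(ValueError):
            SteadyProfileModel(psnd_layers(), q=Q, wt_depth=100.0, obs_depths=[120.0])

    def test_matches_unit_gradient_far_from_water_table(self):
        from drainsim.hydraulics import unit_gradient_state

        m = SteadyProfileModel(
            [(0.0, 300.0, SAND, "g")], q=Q, wt_depth=300.0, obs_depths=[30.0]
        )
        ug = unit_gradient_state(Q, SAND)
        assert m()[0] == pytest.approx(ug.theta, rel=1e-3)
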