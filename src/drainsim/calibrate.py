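"""Inverse modeling: weighted least squares via modified Gauss-Newton,
composite scaled sensitivities (CSS) and RMSE goodness-of-fit.

The fitter is generic: a forward model is any callable mapping a parameter
dict to a simulated vector aligned with an :class:`ObservationSet`.  The
"modification" of Gauss-Newton is Levenberg-style damping engaged only when
an undamped step fails to reduce the objective, so on a linear model the
fit converges in a single accepted step.

Sensitivities are forward finite differences with a 1% relative
perturbation (absolute fallback for zero-valued parameters).  The composite
scaled sensitivity of parameter j over N observations is

    CSS_j = sqrt( (1/N) sum_i [ (d sim_i / d p_j) p_j w_i^(1/2) ]^2 )

and parameters whose CSS ratio to the maximum falls below 0.01 are flagged
as insensitive (a regression including them will not converge).

A fast 1D forward model, :class:`SteadyProfileModel`, integrates the steady
vertical Richards profile dh/dz = 1 - q/K(h) upward from the water table
through a layered column; it supplies moisture "data" at probe depths in
fractions of a second and is the workhorse for parameter-recovery and
sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .hydraulics import VanGenuchtenParams, conductivity_from_head, water_content_from_head

__all__ = [
    "ObservationSet",
    "CalibrationResult",
    "RankDeficiencyError",
    "weighted_sse",
    "rmse",
    "composite_scaled_sensitivity",
    "gauss_newton_fit",
    "SteadyProfileModel",
]

CSS_EXCLUDE_RATIO = 0.01


class RankDeficiencyError(np.linalg.LinAlgError):
    def __init__(self, params: Sequence[str]):
        self.params = list(params)
        super().__init__(
            "singular normal equations; unidentifiable parameter(s): "
            + ", ".join(self.params)
        )


@dataclass
class ObservationSet:
    """Grouped observations (group, time_d, value, sigma); weights 1/sigma^2."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"group", "time_d", "value", "sigma"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"observation table needs columns {sorted(need)}")
        if (self.data["sigma"] <= 0).any():
            raise ValueError("sigma must be positive")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.data["sigma"].to_numpy(float) ** 2

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def rmse_by_group(self, sim: np.ndarray) -> dict[str, float]:
        out = {}
        for grp, sub in self.data.groupby("group"):
            out[str(grp)] = rmse(sim[sub.index.to_numpy()], sub["value"].to_numpy())
        return out


def weighted_sse(params: Mapping[str, float], model: Callable, obs: ObservationSet) -> float:
    """Weighted least-squares objective sum_i w_i (obs_i - sim_i)^2."""
    r = obs.values - np.asarray(model(dict(params)), float)
    return float(np.sum(obs.weights * r**2))


def rmse(sim, obs) -> float:
    sim = np.asarray(sim, float)
    obs = np.asarray(obs, float)
    if sim.size == 0 or sim.shape != obs.shape:
        raise ValueError("series must be non-empty and of equal length")
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def _jacobian(model, params: dict, base: np.ndarray, names, rel: float, abs_step: float):
    J = np.empty((base.size, len(names)))
    for j, name in enumerate(names):
        p0 = params[name]
        dp = rel * abs(p0) if p0 != 0.0 else abs_step
        pp = dict(params)
        pp[name] = p0 + dp
        J[:, j] = (np.asarray(model(pp), float) - base) / dp
    return J


def composite_scaled_sensitivity(
    model: Callable,
    params: Mapping[str, float],
    obs: ObservationSet,
    rel_perturb: float = 0.01,
    abs_step: float = 1e-6,
) -> tuple[dict[str, float], dict[str, float], list[str]]:
    """CSS per parameter, CSS ratios, and the insensitive (ratio < 0.01) list."""
    params = dict(params)
    names = list(params)
    base = np.asarray(model(params), float)
    J = _jacobian(model, params, base, names, rel_perturb, abs_step)
    sw = np.sqrt(obs.weights)
    pvec = np.array([params[n] for n in names])
    css = np.sqrt(np.mean((J * pvec[None, :] * sw[:, None]) ** 2, axis=0))
    cmax = css.max()
    if cmax <= 0.0:
        ratios = np.zeros_like(css)
    else:
        ratios = css / cmax
    excluded = [n for n, r in zip(names, ratios) if r < CSS_EXCLUDE_RATIO]
    return dict(zip(names, css)), dict(zip(names, ratios)), excluded


@dataclass
class CalibrationResult:
    params: dict[str, float]
    objective_history: list[float]
    css: dict[str, float]
    css_ratio: dict[str, float]
    rmse_by_group: dict[str, float]
    converged: bool
    n_accepted_steps: int
    excluded: list[str] = field(default_factory=list)


def gauss_newton_fit(
    model: Callable,
    obs: ObservationSet,
    init: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    max_iter: int = 25,
    rel_perturb: float = 0.01,
    tol_rel_change: float = 1e-3,
    screen_css: bool = False,
) -> CalibrationResult:
    """Damped Gauss-Newton weighted least squares.

    The objective is non-increasing across accepted steps; iteration stops
    when the relative parameter change drops below ``tol_rel_change`` or
    after ``max_iter`` accepted steps.  With ``screen_css=True`` parameters
    with CSS ratio < 0.01 at the initial values are frozen (excluded from
    the regression), mirroring the screening used with composite scaled
    sensitivities.
    """
    params = dict(init)
    names = list(params)
    if len(obs) < len(names):
        raise ValueError("need at least as many observations as free parameters")
    bounds = dict(bounds or {})
    excluded: list[str] = []
    if screen_css:
        _, _, excluded = composite_scaled_sensitivity(model, params, obs, rel_perturb)
        names = [n for n in names if n not in excluded]
        if not names:
            raise RankDeficiencyError(excluded)

    w = obs.weights
    sw = np.sqrt(w)
    y = obs.values

    def clip(p: dict) -> dict:
        for n, (lo, hi) in bounds.items():
            if n in p:
                p[n] = float(np.clip(p[n], lo, hi))
        return p

    sim = np.asarray(model(params), float)
    sse = float(np.sum(w * (y - sim) ** 2))
    history = [sse]
    lam = 0.0
    accepted = 0
    converged = False

    for _ in range(max_iter):
        J = _jacobian(model, params, sim, names, rel_perturb, 1e-6)
        dead = [n for n, col in zip(names, J.T) if np.all(np.abs(col) < 1e-300)]
        if dead:
            raise RankDeficiencyError(dead)
        JW = J * sw[:, None]
        G = JW.T @ JW
        g = JW.T @ (sw * (y - sim))

        improved = False
        for _try in range(12):
            M = G + lam * np.diag(np.maximum(np.diag(G), 1e-30))
            try:
                step = np.linalg.solve(M, g)
            except np.linalg.LinAlgError:
                if lam == 0.0:
                    u, s, vt = np.linalg.svd(G)
                    bad = [names[i] for i in np.where(s < s.max() * 1e-14)[0]]
                    raise RankDeficiencyError(bad or names)
                lam = max(lam * 10.0, 1e-4)
                continue
            trial = clip({**params, **{n: params[n] + d for n, d in zip(names, step)}})
            sim_t = np.asarray(model(trial), float)
            sse_t = float(np.sum(w * (y - sim_t) ** 2))
            if sse_t <= sse * (1.0 + 1e-12):
                rel_change = max(
                    abs(trial[n] - params[n]) / (abs(params[n]) + 1e-30) for n in names
                )
                params, sim, sse = trial, sim_t, sse_t
                history.append(sse)
                accepted += 1
                lam = lam / 3.0 if lam > 1e-8 else 0.0
                improved = True
                if rel_change < tol_rel_change or sse <= 1e-14 * max(history[0], 1e-300):
                    converged = True
                break
            lam = max(lam * 10.0, 1e-4)
        if converged or not improved:
            converged = converged or not improved and sse <= history[0]
            break

    css, ratios, _ = composite_scaled_sensitivity(model, params, obs, rel_perturb)
    return CalibrationResult(
        params=params,
        objective_history=history,
        css=css,
        css_ratio=ratios,
        rmse_by_group=obs.rmse_by_group(sim),
        converged=converged,
        n_accepted_steps=accepted,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# fast steady 1D forward model
# ---------------------------------------------------------------------------


class SteadyProfileModel:
    """Steady vertical moisture profile of a layered column under constant
    downward flux ``q`` (cm/d) with a water table at ``wt_depth`` (cm bgs).

    ``layers`` is a list of ``(z_top, z_bottom, VanGenuchtenParams, tag)``;
    free parameters are addressed as ``"<tag>.<field>"`` (e.g.
    ``"s.theta_s"``).  Calling the model with a parameter dict returns the
    water content at ``obs_depths`` (cm bgs).
    """

    def __init__(self, layers, q: float, wt_depth: float, obs_depths: Sequence[float]):
        self.layers = list(layers)
        self.q = float(q)
        self.wt_depth = float(wt_depth)
        self.obs_depths = np.asarray(obs_depths, float)
        if np.any(self.obs_depths >= self.wt_depth):
            raise ValueError("observation depths must lie above the water table")

    def _vg_at(self, depth: float, params: Mapping[str, float]) -> VanGenuchtenParams:
        for i, (z0, z1, vg, tag) in enumerate(self.layers):
            if z0 <= depth < z1 or (i == len(self.layers) - 1 and depth >= z1):
                over = {
                    k.split(".", 1)[1]: v
                    for k, v in params.items()
                    if k.startswith(tag + ".")
                }
                return replace(vg, **over) if over else vg
        raise ValueError(f"depth {depth} not covered by any layer")

    def profile(self, params: Mapping[str, float] | None = None):
        """(depths, h, theta) from the water table up to the surface."""
        params = dict(params or {})
        q = params.pop("q", self.q)

        def rhs(s, h):
            depth = self.wt_depth - s
            vg = self._vg_at(max(depth, 0.0), params)
            K = max(conductivity_from_head(h[0], vg), 1e-12)
            return [q / K - 1.0]

        s_eval = np.unique(self.wt_depth - self.obs_depths)
        sol = solve_ivp(
            rhs, (0.0, self.wt_depth), [0.0], method="Radau",
            t_eval=s_eval, max_step=2.0, rtol=1e-8, atol=1e-8,
        )
        if not sol.success:
            raise RuntimeError(f"steady-profile integration failed: {sol.message}")
        depths = self.wt_depth - sol.t
        h = sol.y[0]
        theta = np.array(
            [water_content_from_head(hv, self._vg_at(d, params)) for hv, d in zip(h, depths)]
        )
        return depths, h, theta

    def __call__(self, params: Mapping[str, float] | None = None) -> np.ndarray:
        depths, _, theta = self.profile(params)
        lookup = {round(d, 9): t for d, t in zip(depths, theta)}
        return np.array([lookup[round(d, 9)] for d in self.obs_depths])
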