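"""Mesocosm model domains: mesh, materials, boundaries, observation nodes.

The physical mesocosms are 15-cm-ID, 1.5-m soil columns; the model domain
is a 2D vertical plane (x horizontal, z in cm below the ground surface,
increasing downward), 15 x 137 cm, discretized on a structured
quadrilateral grid with local refinement (element size down to 0.45 cm)
around the distribution pipe / cover and coarse elements (<= 3.9 cm)
elsewhere.  Cell-centered finite volumes are used by the solvers.

Boundary conditions follow the experimental operation: atmospheric top (no
rain or evaporation, so effectively no-flux), no-flux sides and bottom
except a single seepage-face node at the bottom that discharges only when
locally saturated (a hanging water table), and a variable-flux segment at
the infiltrative surface where effluent is dosed (the full width for PSND,
a pipe-wide segment for GEO and P&S).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import presets
from .hydraulics import VanGenuchtenParams, unit_gradient_state
from .kinetics import (
    DenitrificationParams,
    NitrificationParams,
    mu_max_from_effective_rate,
)

__all__ = [
    "MaterialZone",
    "Domain",
    "FlowConfig",
    "build_mesocosm",
    "build_column",
    "assign_boundaries",
    "place_observation_nodes",
    "write_vtk",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class MaterialZone:
    """A region of the domain binding hydraulic, transport and kinetic
    parameters.

    ``lambda_L``/``lambda_T`` are longitudinal/transverse dispersivities
    (cm); ``D_free`` maps species name to free-water diffusion (cm^2/day);
    ``Kd`` is the linear sorption coefficient (cm^3/g, 0 = no sorption);
    ``native`` marks calibrated native-soil horizons (reported in WFPS
    summaries), as opposed to engineered fill or backfill.
    """

    name: str
    vg: VanGenuchtenParams
    rho_b: float = 1.5
    lambda_L: float = 10.0
    lambda_T: float = 1.0
    D_free: Mapping[str, float] = field(
        default_factory=lambda: {k: v * 24.0 for k, v in presets.D_FREE_CM2_PER_H.items()}
    )
    Kd: float = 0.0
    nit: NitrificationParams | None = None
    denit: DenitrificationParams | None = None
    native: bool = True

    def __post_init__(self) -> None:
        if self.lambda_L <= 0.0 or self.lambda_T < 0.0:
            raise GeometryError("require lambda_L > 0 and lambda_T >= 0")
        if self.rho_b <= 0.0 or self.Kd < 0.0:
            raise GeometryError("require rho_b > 0 and Kd >= 0")


@dataclass(frozen=True)
class ObservationNode:
    name: str
    depth_bgs: float  # cm below ground surface
    depth_below_is: float
    iz: int
    ix: int


@dataclass
class FlowConfig:
    """Run controls for the flow solver.

    ``h_init`` is the uniform initial pressure head (cm); ``h_crit_min`` the
    minimum permissible pressure at the atmospheric boundary; ``t_end`` the
    simulated period (days).  ``seepage_pool_height`` (cm above the domain
    bottom) sets the level the seepage face maintains once saturated -- 0
    reproduces the baseline single bottom node, larger values emulate a
    raised water table.  ``sink`` is the root-uptake term, fixed 0 here.
    ``temperature`` (deg C) is constant per run and is consumed by the
    kinetics.  ``axisymmetric`` weights volumes/faces by 2*pi*x (x then
    being the radius); default off matches the plane-domain convention.
    """

    h_init: float = -50.0
    h_crit_min: float = -1000.0
    t_end: float = 90.0
    temperature: float = 20.0
    seepage_pool_height: float = 0.0
    sink: float = 0.0
    axisymmetric: bool = False
    anisotropy: tuple[float, float] = (1.0, 1.0)  # (Kxx, Kzz) multipliers
    # numerics
    dt_init: float = 1e-4
    dt_min: float = 1e-8
    dt_max: float = 0.5
    picard_tol: float = 1e-6
    theta_tol: float = 1e-8   # water-content residual acceptance (mixed form)
    max_picard: int = 60
    max_head_change: float = 20.0   # cm, per-iteration update clamp
    internodal: str = "arithmetic"  # or "geometric" / "upstream"
    specific_storage: float = 1e-5  # 1/cm, saturated cells only

    def __post_init__(self) -> None:
        if self.sink != 0.0:
            raise GeometryError("a nonzero sink term is not supported")
        if not (self.h_crit_min < self.h_init < 0.0):
            raise GeometryError("require h_crit_min < h_init < 0")
        if self.t_end <= 0.0:
            raise GeometryError("t_end must be positive")


class Domain:
    """Structured-grid mesocosm domain (cell-centered finite volumes)."""

    def __init__(
        self,
        system: str,
        x_edges: np.ndarray,
        z_edges: np.ndarray,
        materials: Sequence[MaterialZone],
        material_id: np.ndarray,
        infiltrative_depth: float,
    ) -> None:
        self.system = system
        self.x_edges = np.asarray(x_edges, float)
        self.z_edges = np.asarray(z_edges, float)
        self.materials = list(materials)
        self.material_id = np.asarray(material_id, int)
        self.infiltrative_depth = float(infiltrative_depth)
        self.nz = len(self.z_edges) - 1
        self.nx = len(self.x_edges) - 1
        if self.material_id.shape != (self.nz, self.nx):
            raise GeometryError("material map does not tile the mesh")
        self.dx = np.diff(self.x_edges)
        self.dz = np.diff(self.z_edges)
        self.xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        self.zc = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        # filled by assign_boundaries / place_observation_nodes
        self.boundaries: dict[str, dict] = {}
        self.flux_cells: np.ndarray | None = None
        self.flux_width: float = 0.0
        self.seepage_cell: tuple[int, int] | None = None
        self.observation_nodes: list[ObservationNode] = []

    # -- basic metrics ------------------------------------------------------

    @property
    def width(self) -> float:
        return float(self.x_edges[-1] - self.x_edges[0])

    @property
    def height(self) -> float:
        return float(self.z_edges[-1] - self.z_edges[0])

    @property
    def node_count(self) -> int:
        return (self.nx + 1) * (self.nz + 1)

    def cell_areas(self) -> np.ndarray:
        return np.outer(self.dz, self.dx)

    def depth_below_is(self) -> np.ndarray:
        """Cell-center depth below the infiltrative surface, clipped at 0."""
        z = np.maximum(self.zc - self.infiltrative_depth, 0.0)
        return np.broadcast_to(z[:, None], (self.nz, self.nx)).copy()

    def material_property_grid(self, getter) -> np.ndarray:
        """Evaluate ``getter(material)`` per cell, returning an (nz, nx) grid."""
        vals = np.array([getter(m) for m in self.materials], dtype=float)
        return vals[self.material_id]

    def material_mask(self, name: str) -> np.ndarray:
        idx = [i for i, m in enumerate(self.materials) if m.name == name]
        if not idx:
            raise GeometryError(f"no material named {name!r}")
        return np.isin(self.material_id, idx)

    def boundary_perimeter_lengths(self) -> dict[str, float]:
        """Lengths of the outer boundary segments; they tile the perimeter."""
        return {k: v["length"] for k, v in self.boundaries.items() if v.get("outer")}

    def nearest_cell(self, x: float, z: float) -> tuple[int, int]:
        if not (self.z_edges[0] <= z <= self.z_edges[-1]):
            raise GeometryError(f"depth {z} cm outside domain of height {self.height}")
        if not (self.x_edges[0] <= x <= self.x_edges[-1]):
            raise GeometryError(f"x={x} outside domain of width {self.width}")
        iz = int(np.argmin(np.abs(self.zc - z)))
        ix = int(np.argmin(np.abs(self.xc - x)))
        return iz, ix


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------


def _graded_edges(
    breaks: Sequence[float],
    fine_bands: Sequence[tuple[float, float]],
    dz_fine: float,
    dz_max: float,
    grade: float = 0.5,
) -> np.ndarray:
    """1D edge coordinates honouring hard breakpoints and refinement bands.

    Spacing is ``dz_fine`` inside any band and grows linearly with distance
    from the nearest band up to ``dz_max``.
    """

    def target(z: np.ndarray) -> np.ndarray:
        if not fine_bands:
            return np.full_like(z, dz_max)
        dist = np.min(
            [np.maximum(np.maximum(a - z, z - b), 0.0) for a, b in fine_bands], axis=0
        )
        return np.minimum(dz_max, dz_fine + grade * dist)

    # equidistribute the spacing density 1/target over each interval: cells
    # track the target size smoothly and fit the breakpoints exactly
    edges = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        xs = np.linspace(a, b, 1601)
        dens = 1.0 / target(xs)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(xs))])
        n = max(1, int(round(cum[-1])))
        levels = cum[-1] * np.arange(1, n + 1) / n
        edges.extend(np.interp(levels, cum, xs))
    return np.array(edges)


def _x_edges_localized(width: float, pipe_diameter: float) -> np.ndarray:
    """Lateral edges with a pipe-wide pair of central cells."""
    c = width / 2.0
    r = pipe_diameter / 2.0
    inner = [c - r, c, c + r]
    left = np.linspace(0.0, c - r, 4)[:-1]
    right = np.linspace(c + r, width, 4)[1:]
    return np.concatenate([left, inner, right])


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------


def _default_kinetics(system: str, mean_flux: float):
    """Per-material kinetics with mu_max tuned so the effective zero-order
    rate at the layer's reference state (modeled WFPS, 20 deg C, layer
    mid-depth) equals the published layer average."""
    sysname = presets.canonical_system(system)
    is_depth = presets.INFILTRATIVE_DEPTH[sysname]
    out: dict[str, tuple[NitrificationParams, DenitrificationParams]] = {}

    def ref_state(mat: str) -> tuple[float, float]:
        ref = presets.WFPS_REFERENCE.get(sysname, {})
        if mat in ref:
            s = ref[mat][0]
        else:  # engineered fill: unit-gradient state at the mean flux
            vg = presets.COARSE_FILL
            s = unit_gradient_state(min(mean_flux, vg.Ks), vg).wfps
        if mat == "silt_loam":
            zmid = max(0.0, 0.5 * (presets.SILT_SAND_INTERFACE - is_depth))
        elif mat == "gravelly_sand":
            top = max(presets.SILT_SAND_INTERFACE, is_depth)
            zmid = 0.5 * (top + presets.DOMAIN_HEIGHT) - is_depth
        else:
            zmid = 0.0
        return s, zmid

    for mat, rate in presets.NITRIFICATION_RATES[sysname].items():
        s, zmid = ref_state(mat)
        nit = mu_max_from_effective_rate(rate, s, 20.0, NitrificationParams())
        dr = presets.DENITRIFICATION_RATES[sysname][mat]
        den = mu_max_from_effective_rate(
            dr, s, 20.0, DenitrificationParams(), z=zmid
        )
        out[mat] = (nit, den)
    return out


def _layers_for(system: str) -> list[tuple[float, float, str, VanGenuchtenParams, float, bool]]:
    """(z_top, z_bottom, material name, vg, rho_b, native) per horizon."""
    H = presets.DOMAIN_HEIGHT
    iface = presets.SILT_SAND_INTERFACE
    if system == "PSND":
        return [
            (0.0, iface, "silt_loam", presets.SILT_LOAM["PSND"], presets.RHO_B["silt_loam"], True),
            (iface, H, "gravelly_sand", presets.GRAVELLY_SAND["PSND"], presets.RHO_B["gravelly_sand"], True),
        ]
    if system == "GEO":
        fil_top = presets.INFILTRATIVE_DEPTH["GEO"]
        fil_bot = fil_top + presets.FILAMENT_THICKNESS
        return [
            (0.0, fil_top, "silt_loam", presets.SILT_LOAM["GEO"], presets.RHO_B["silt_loam"], True),
            (fil_top, fil_bot, "coarse_fill", presets.COARSE_FILL, presets.RHO_B["coarse_fill"], False),
            (fil_bot, iface, "silt_loam", presets.SILT_LOAM["GEO"], presets.RHO_B["silt_loam"], True),
            (iface, H, "gravelly_sand", presets.GRAVELLY_SAND["GEO"], presets.RHO_B["gravelly_sand"], True),
        ]
    if system == "P&S":
        return [
            (0.0, presets.STONE_TOP, "backfill", presets.SILT_LOAM_GENERIC, presets.RHO_B["silt_loam"], False),
            (presets.STONE_TOP, presets.STONE_BOTTOM, "coarse_fill", presets.COARSE_FILL, presets.RHO_B["coarse_fill"], False),
            (presets.STONE_BOTTOM, H, "gravelly_sand", presets.GRAVELLY_SAND["P&S"], presets.RHO_B["gravelly_sand"], True),
        ]
    raise GeometryError(f"unknown system {system!r}")


def build_mesocosm(system_type: str, overrides: Mapping | None = None) -> Domain:
    """Build the full mesh + material + boundary + observation-node domain
    for one of the three mesocosm types (``PSND``, ``GEO``, ``P&S``).

    ``overrides`` may replace ``width``, ``height``, ``materials`` (a list
    of ``(z_top, z_bottom, MaterialZone)``), ``infiltrative_depth``,
    ``dz_fine``, ``dz_max``, ``flux_width`` and ``attach_kinetics``.
    """
    ov = dict(overrides or {})
    system = presets.canonical_system(system_type)
    width = float(ov.pop("width", presets.DOMAIN_WIDTH))
    height = float(ov.pop("height", presets.DOMAIN_HEIGHT))
    is_depth = float(ov.pop("infiltrative_depth", presets.INFILTRATIVE_DEPTH[system]))
    dz_fine = float(ov.pop("dz_fine", 0.42))
    dz_max = float(ov.pop("dz_max", 3.5))
    flux_width = ov.pop("flux_width", None)
    attach_kinetics = bool(ov.pop("attach_kinetics", True))
    custom_layers = ov.pop("materials", None)
    if ov:
        raise GeometryError(f"unknown overrides: {sorted(ov)}")

    lamL = presets.dispersivity_L(system)
    dosing = presets.DOSING[system]
    mean_flux = dosing["volume"] / dosing["period"] / presets.MESOCOSM_AREA_CM2

    if custom_layers is not None:
        layers = [(a, b, mz) for (a, b, mz) in custom_layers]
        materials = []
        spans = []
        for a, b, mz in layers:
            materials.append(mz)
            spans.append((a, b))
    else:
        kin = _default_kinetics(system, mean_flux) if attach_kinetics else {}
        materials, spans = [], []
        for a, b, name, vg, rho, native in _layers_for(system):
            nit, den = kin.get(name, (None, None))
            materials.append(
                MaterialZone(
                    name=name, vg=vg, rho_b=rho, lambda_L=lamL,
                    lambda_T=lamL / 10.0, nit=nit, denit=den, native=native,
                )
            )
            spans.append((a, b))

    # vertical mesh: hard breaks at horizon boundaries; fine bands around
    # the pipe / cover and the infiltrative surface
    breaks = sorted({0.0, height, *[s for ab in spans for s in ab if 0.0 < s < height]})
    # PSND: wide refinement under the arc cover; P&S: the stone layer above
    # the IS is already conductive fill, so a narrow band suffices
    half = {"PSND": 4.0, "GEO": 2.0, "P&S": 1.0}.get(system, 2.0)
    bands = [(max(0.0, is_depth - half), min(height, is_depth + half))]
    # sharp material contrasts develop thin boundary layers: refine there
    iface_z = presets.SILT_SAND_INTERFACE
    if custom_layers is None and system in ("PSND", "GEO"):
        bands.append((iface_z - 2.0, iface_z + 2.0))
    if system in presets.PIPE_DEPTH:
        pc = presets.PIPE_DEPTH[system]
        r = presets.PIPE_DIAMETER / 2.0 + 0.5
        bands.append((max(0.0, pc - r), min(height, pc + r)))
    z_edges = _graded_edges(breaks, bands, dz_fine, dz_max)

    if system == "PSND":
        x_edges = np.linspace(0.0, width, 9)
    else:
        x_edges = _x_edges_localized(width, presets.PIPE_DIAMETER)

    nz, nx = len(z_edges) - 1, len(x_edges) - 1
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    material_id = np.zeros((nz, nx), dtype=int)
    covered = np.zeros(nz, dtype=bool)
    for mid, (a, b) in enumerate(spans):
        rows = (zc >= a) & (zc < b)
        material_id[rows, :] = mid
        covered |= rows
    material_id[zc >= spans[-1][1], :] = len(spans) - 1  # guard rounding at bottom
    if not covered.all() and custom_layers is not None:
        raise GeometryError("material zones do not tile the domain")

    dom = Domain(system, x_edges, z_edges, materials, material_id, is_depth)
    assign_boundaries(dom, system, flux_width=flux_width)
    place_observation_nodes(dom)
    return dom


def build_column(
    vg: VanGenuchtenParams,
    height: float = 100.0,
    nz: int = 100,
    width: float = 15.0,
    nx: int = 1,
    infiltrative_depth: float = 0.0,
    material: MaterialZone | None = None,
) -> Domain:
    """Homogeneous column domain for verification tests and 1D oracles."""
    mat = material or MaterialZone(name="soil", vg=vg, lambda_L=0.1 * height)
    z_edges = np.linspace(0.0, height, nz + 1)
    x_edges = np.linspace(0.0, width, nx + 1)
    dom = Domain("column", x_edges, z_edges, [mat], np.zeros((nz, nx), int), infiltrative_depth)
    assign_boundaries(dom, "column", flux_width=None)
    depths = [d for d in presets.OBSERVATION_DEPTHS_BELOW_IS if infiltrative_depth + d < height]
    place_observation_nodes(dom, depths_below_is=depths)
    return dom


def assign_boundaries(domain: Domain, system_type: str, flux_width: float | None = None) -> Domain:
    """Attach boundary conditions: atmospheric top, no-flux sides/bottom, one
    bottom seepage-face node, and the effluent variable-flux segment (full
    infiltrative width for PSND and homogeneous columns, a pipe-wide segment
    below the distribution pipe for GEO and P&S)."""
    if domain.nz == 0:
        raise GeometryError("domain has no mesh")
    nz, nx = domain.nz, domain.nx
    w, h = domain.width, domain.height

    # flux segment: cells in the row just below the infiltrative surface
    iz_is = int(np.searchsorted(domain.z_edges, domain.infiltrative_depth + 1e-9)) if domain.infiltrative_depth > 0 else 0
    iz_is = min(iz_is, nz - 1)
    localized = system_type in ("GEO", "P&S")
    if localized:
        seg_w = flux_width if flux_width is not None else presets.PIPE_DIAMETER
        c = w / 2.0
        cols = np.where(np.abs(domain.xc - c) <= seg_w / 2.0 + 1e-9)[0]
        if len(cols) == 0:
            cols = np.array([int(np.argmin(np.abs(domain.xc - c)))])
    else:
        cols = np.arange(nx)
    domain.flux_cells = np.array([(iz_is, ix) for ix in cols])
    domain.flux_width = float(domain.dx[cols].sum())

    seep_ix = nx // 2
    domain.seepage_cell = (nz - 1, seep_ix)
    seep_w = float(domain.dx[seep_ix])

    domain.boundaries = {
        "top": dict(condition="atmospheric", length=w, outer=True),
        "left": dict(condition="no_flux", length=h, outer=True),
        "right": dict(condition="no_flux", length=h, outer=True),
        "bottom_no_flux": dict(condition="no_flux", length=w - seep_w, outer=True),
        "seepage_face": dict(condition="seepage_face", length=seep_w, outer=True),
        "infiltrative_flux": dict(condition="variable_flux", length=domain.flux_width, outer=False),
    }
    return domain


def place_observation_nodes(
    domain: Domain, depths_below_is: Sequence[float] = presets.OBSERVATION_DEPTHS_BELOW_IS
) -> Domain:
    """Observation nodes at the probe depths below the infiltrative surface,
    at the domain bottom, and at the column outlet (the seepage node)."""
    nodes: list[ObservationNode] = []
    cx = domain.width / 2.0
    for d in depths_below_is:
        z = domain.infiltrative_depth + d
        iz, ix = domain.nearest_cell(cx, z)  # raises if outside the domain
        nodes.append(ObservationNode(f"probe_{d:g}cm", z, d, iz, ix))
    iz, ix = domain.nearest_cell(cx, domain.height)
    nodes.append(
        ObservationNode("bottom", domain.height, domain.height - domain.infiltrative_depth, iz, ix)
    )
    if domain.seepage_cell is not None:
        sz, sx = domain.seepage_cell
        nodes.append(
            ObservationNode("outlet", domain.height, domain.height - domain.infiltrative_depth, sz, sx)
        )
    domain.observation_nodes = nodes
    return domain


def write_vtk(domain: Domain, path: str, cell_fields: Mapping[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional cell fields) as a legacy-ASCII VTK
    rectilinear grid, for inspection in ParaView and friends."""
    fields = cell_fields or {}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"drainsim {domain.system} domain\nASCII\nDATASET RECTILINEAR_GRID\n")
        f.write(f"DIMENSIONS {domain.nx + 1} {domain.nz + 1} 1\n")
        f.write(f"X_COORDINATES {domain.nx + 1} float\n")
        f.write(" ".join(f"{x:.6g}" for x in domain.x_edges) + "\n")
        f.write(f"Y_COORDINATES {domain.nz + 1} float\n")
        # VTK y is upward: flip depth to elevation
        f.write(" ".join(f"{domain.height - z:.6g}" for z in domain.z_edges) + "\n")
        f.write("Z_COORDINATES 1 float\n0\n")
        f.write(f"CELL_DATA {domain.nz * domain.nx}\n")
        mats = {"material": domain.material_id.astype(float), **fields}
        for name, arr in mats.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for iz in range(domain.nz - 1, -1, -1):  # flip rows for upward y
                f.write(" ".join(f"{v:.6g}" for v in np.asarray(arr)[iz]) + "\n")
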