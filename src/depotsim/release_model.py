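"""Forward simulation of drug release in a transwell insert/well system.

The physical picture: a drug depot (bolus solution, liposome suspension, or a
liposome-alginate composite treated as one homogeneous layer with a single
effective diffusivity) sits at the top of a transwell insert. Drug diffuses
down through the insert medium, across the permeable membrane, and into the
bottom well where the cells reside. The culture plate is quiescent, so the
steady flow field is zero and transport is pure Fickian diffusion; a hook for
a finite membrane permeability is provided for membrane-limited systems.

The 3D well is reduced to a 1D axial finite-volume model with a
cross-sectional-area jump at the insert-well interface. Finite volumes make
the discrete mass bookkeeping exact: the total drug amount is conserved to
round-off at every step. No-flux conditions hold at the top of the insert and
the bottom of the well; the only open interface is the membrane.

Concentrations are expressed in mM throughout, which is numerically identical
to the SI mol/m^3. Lengths and areas are SI (m, m^2); times are seconds
internally with hours at the interface where the assay schedule is specified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import NumericalError, ValidationError

logger = logging.getLogger("depotsim")

#: Concentrations more negative than this (in mM) indicate solver failure;
#: anything between -NEGATIVE_FLOOR and 0 is round-off and is clipped to 0.
NEGATIVE_FLOOR_MM = 1e-12

HOUR = 3600.0
DAY = 86400.0

ConstructForm = Literal["bolus", "liposome", "liposome_alginate"]
Scheme = Literal["backward_euler", "crank_nicolson"]


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranswellGeometry:
    """Physical description of the insert/well system.

    Parameters
    ----------
    insert_membrane_area : float
        Cross-sectional (membrane) area of the insert, m^2. The insert fluid
        column is modelled with this area.
    insert_fluid_depth : float
        Depth of fluid in the insert, m.
    well_cross_area : float
        Cross-sectional area of the bottom well, m^2.
    well_fluid_depth : float
        Depth of fluid in the bottom well below the membrane, m.
    depot_thickness : float
        Thickness of the drug depot layer at the top of the insert, m.
        Must not exceed ``insert_fluid_depth``.
    plate_format : {"well24", "well96"}
        Plate format label (metadata; the dimensions above are authoritative).
    membrane_permeability : float or None
        Optional membrane permeability in m/s. ``None`` means the membrane is
        freely permeable (interface continuity, the default: the membrane is
        assigned no resistance).
    """

    insert_membrane_area: float
    insert_fluid_depth: float
    well_cross_area: float
    well_fluid_depth: float
    depot_thickness: float
    plate_format: str = "well24"
    membrane_permeability: float | None = None

    def __post_init__(self):
        for name in ("insert_membrane_area", "insert_fluid_depth",
                     "well_cross_area", "well_fluid_depth", "depot_thickness"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, f"{name} must be finite and > 0, got {v!r}")
        _require(self.depot_thickness <= self.insert_fluid_depth * (1 + 1e-12),
                 "depot_thickness must not exceed insert_fluid_depth")
        _require(self.plate_format in ("well24", "well96"),
                 f"plate_format must be 'well24' or 'well96', got {self.plate_format!r}")
        if self.membrane_permeability is not None:
            _require(self.membrane_permeability > 0,
                     "membrane_permeability must be > 0 (or None for no resistance)")

    @property
    def insert_volume(self) -> float:
        """Total insert fluid volume, m^3 (includes the depot layer)."""
        return self.insert_membrane_area * self.insert_fluid_depth

    @property
    def well_volume(self) -> float:
        """Bottom-well fluid volume, m^3."""
        return self.well_cross_area * self.well_fluid_depth

    @property
    def depot_volume(self) -> float:
        """Depot layer volume, m^3."""
        return self.insert_membrane_area * self.depot_thickness


@dataclass(frozen=True)
class DrugProperties:
    """Transport properties of the drug in free culture medium."""

    name: str
    diffusivity_media: float  # m^2/s
    molar_mass: float | None = None  # g/mol, metadata only
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        _require(np.isfinite(self.diffusivity_media) and self.diffusivity_media > 0,
                 "diffusivity_media must be finite and > 0")


@dataclass(frozen=True)
class ConstructSpec:
    """The drug depot: its form, loading and effective transport coefficient.

    ``effective_diffusivity`` is the single coefficient summarising drug
    escape through the depot layer; for a bolus it must equal the drug's
    media diffusivity (checked at simulation time against ``DrugProperties``).
    """

    form: ConstructForm
    initial_concentration: float  # mM
    effective_diffusivity: float  # m^2/s
    depot_volume: float | None = None  # m^3; derived from geometry if None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        _require(self.form in ("bolus", "liposome", "liposome_alginate"),
                 f"unknown construct form {self.form!r}")
        _require(self.initial_concentration >= 0,
                 "initial_concentration must be >= 0")
        _require(np.isfinite(self.effective_diffusivity) and self.effective_diffusivity > 0,
                 "effective_diffusivity must be finite and > 0")
        if self.depot_volume is not None:
            _require(self.depot_volume > 0, "depot_volume must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Time stepping and discretisation controls.

    dt is in seconds (default 10 s); output_times are in hours, matching the
    sampling schedule of the release assay. Each output time must be an
    integer number of steps from the previous one.
    """

    dt: float = 10.0
    t_end: float = 96 * HOUR
    output_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 12.0, 24.0, 48.0, 96.0)
    nodes_depot: int = 20
    nodes_media: int = 40
    scheme: Scheme = "backward_euler"
    #: Geometric ratio between adjacent depot cell widths, coarsest at the
    #: depot top and finest at the depot-media interface where the slow-depot/
    #: fast-media diffusivity jump creates a steep front. 1.0 = uniform.
    depot_grading: float = 1.35

    def __post_init__(self):
        _require(self.dt > 0, "dt must be > 0")
        _require(self.t_end > 0, "t_end must be > 0")
        ot = np.asarray(self.output_times, dtype=float)
        _require(ot.size >= 1, "output_times must be nonempty")
        _require(np.all(np.diff(ot) > 0), "output_times must be strictly increasing")
        _require(np.all(ot >= 0), "output_times must be non-negative")
        _require(ot[-1] * HOUR <= self.t_end * (1 + 1e-9),
                 "all output_times must be <= t_end")
        _require(self.nodes_depot >= 3, "nodes_depot must be >= 3")
        _require(self.nodes_media >= 3, "nodes_media must be >= 3")
        _require(self.scheme in ("backward_euler", "crank_nicolson"),
                 f"unknown scheme {self.scheme!r}")
        _require(self.depot_grading >= 1.0, "depot_grading must be >= 1")
        object.__setattr__(self, "output_times", tuple(float(t) for t in ot))


@dataclass(frozen=True)
class ConcentrationField:
    """Axial concentration profile at one instant."""

    node_positions: np.ndarray  # m, cell centres, strictly increasing
    node_concentrations: np.ndarray  # mM, >= 0
    time: float  # s

    def __post_init__(self):
        z = np.asarray(self.node_positions, float)
        c = np.asarray(self.node_concentrations, float)
        _require(z.shape == c.shape, "positions/concentrations length mismatch")
        _require(np.all(np.diff(z) > 0), "node_positions must be strictly increasing")
        _require(np.all(c >= 0), "concentrations must be non-negative")
        object.__setattr__(self, "node_positions", z)
        object.__setattr__(self, "node_concentrations", c)


@dataclass(frozen=True)
class ReleaseCurve:
    """Time course of bottom-well drug concentration and fraction released.

    The central exchange format between the solver, the diffusivity fitter
    and the safety classifier. ``fraction_released`` is the drug amount in
    the bottom well divided by the initial amount loaded in the insert.
    """

    times: np.ndarray  # h
    well_concentration: np.ndarray  # mM
    fraction_released: np.ndarray  # dimensionless in [0, 1]

    def __post_init__(self):
        t = np.asarray(self.times, float)
        c = np.asarray(self.well_concentration, float)
        f = np.asarray(self.fraction_released, float)
        _require(t.shape == c.shape == f.shape, "ReleaseCurve arrays must have equal length")
        _require(np.all(np.diff(t) > 0), "times must be strictly increasing")
        _require(np.all(c >= 0), "well_concentration must be non-negative")
        _require(np.all((f >= -1e-12) & (f <= 1 + 1e-9)),
                 "fraction_released must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "well_concentration", c)
        object.__setattr__(self, "fraction_released", np.clip(f, 0.0, 1.0))

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mesh:
    """1D axial finite-volume mesh spanning depot top to well bottom."""

    z: np.ndarray         # cell centres, m (z increases downward from depot top)
    dz: np.ndarray        # cell widths, m
    area: np.ndarray      # per-cell cross-sectional area, m^2
    domain: np.ndarray    # per-cell label in {depot, insert_media, well_media}
    membrane_face: int    # face index between insert and well regions

    @property
    def cell_volumes(self) -> np.ndarray:
        return self.area * self.dz

    @property
    def n_cells(self) -> int:
        return self.z.size

    def mass(self, concentrations: np.ndarray) -> float:
        """Total drug amount on the mesh, in mM*m^3 (== mmol/1000 ~ mol units)."""
        return float(np.dot(np.asarray(concentrations, float), self.cell_volumes))

    def domain_mass(self, concentrations: np.ndarray, label: str) -> float:
        sel = self.domain == label
        return float(np.dot(np.asarray(concentrations, float)[sel],
                            self.cell_volumes[sel]))


def build_mesh(geometry: TranswellGeometry, config: SimulationConfig) -> Mesh:
    """Build the axial finite-volume mesh for a transwell geometry.

    The depot occupies the top ``depot_thickness`` of the insert; the rest of
    the insert fluid is ``insert_media``; the bottom well is ``well_media``
    with its own (usually larger) cross-sectional area. ``nodes_media`` is
    split between the two media regions in proportion to their depths.

    Depot cells are geometrically graded (``config.depot_grading``) with the
    finest cell at the depot-media interface: for a slow depot the release is
    controlled by a thin boundary layer of width ~sqrt(D_eff * t) there, far
    thinner than a uniform cell at practical node counts.
    """
    L_depot = geometry.depot_thickness
    L_im = geometry.insert_fluid_depth - geometry.depot_thickness
    L_well = geometry.well_fluid_depth
    if L_im < 1e-15:  # depot fills the entire insert
        L_im = 0.0

    nd = config.nodes_depot
    if L_im == 0.0:
        ni, nw = 0, config.nodes_media
    else:
        ni = int(round(config.nodes_media * L_im / (L_im + L_well)))
        ni = min(max(ni, 1), config.nodes_media - 1)
        nw = config.nodes_media - ni

    r = config.depot_grading
    if r == 1.0:
        depot_widths = np.full(nd, L_depot / nd)
    else:
        w_min = L_depot * (r - 1.0) / (r ** nd - 1.0)
        depot_widths = w_min * r ** np.arange(nd - 1, -1, -1)  # coarse top -> fine bottom

    widths, areas, labels = [], [], []
    for w, a, lab in (
        (depot_widths, geometry.insert_membrane_area, "depot"),
        (np.full(ni, L_im / ni) if ni else None, geometry.insert_membrane_area,
         "insert_media"),
        (np.full(nw, L_well / nw), geometry.well_cross_area, "well_media"),
    ):
        if w is None or w.size == 0:
            continue
        widths.append(w)
        areas.append(np.full(w.size, a))
        labels.append(np.full(w.size, lab, dtype=object))

    dz = np.concatenate(widths)
    area = np.concatenate(areas)
    domain = np.concatenate(labels)
    edges = np.concatenate([[0.0], np.cumsum(dz)])
    z = 0.5 * (edges[:-1] + edges[1:])
    membrane_face = int(np.sum(domain != "well_media")) - 1  # face below last insert cell
    return Mesh(z=z, dz=dz, area=area, domain=domain, membrane_face=membrane_face)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationResult:
    """Bundle of everything a forward run produces."""

    curve: ReleaseCurve
    fields: list[ConcentrationField]
    mesh: Mesh
    geometry: TranswellGeometry
    construct: ConstructSpec
    diagnostics: dict


def _diffusion_operator(mesh: Mesh, geometry: TranswellGeometry,
                        drug: DrugProperties, construct: ConstructSpec) -> np.ndarray:
    """Dense finite-volume operator M with dC/dt = M C.

    Face conductances g = A_f / (dz_i/(2 D_i) + dz_j/(2 D_j)) implement flux
    continuity with harmonic averaging of the piecewise diffusivity; the
    membrane face additionally carries a 1/(P*A) series resistance when a
    finite permeability is set. Column sums of (V_i M_ij) vanish, so the
    discrete total mass is invariant.
    """
    n = mesh.n_cells
    D = np.where(mesh.domain == "depot", construct.effective_diffusivity,
                 drug.diffusivity_media).astype(float)
    g = np.empty(n - 1)
    for f in range(n - 1):
        a_face = min(mesh.area[f], mesh.area[f + 1])
        resistance = mesh.dz[f] / (2 * D[f]) + mesh.dz[f + 1] / (2 * D[f + 1])
        g[f] = a_face / resistance
        if f == mesh.membrane_face and geometry.membrane_permeability is not None:
            p_area = geometry.membrane_permeability * geometry.insert_membrane_area
            g[f] = 1.0 / (1.0 / g[f] + 1.0 / p_area)

    V = mesh.cell_volumes
    M = np.zeros((n, n))
    for f in range(n - 1):
        M[f, f] -= g[f] / V[f]
        M[f, f + 1] += g[f] / V[f]
        M[f + 1, f + 1] -= g[f] / V[f + 1]
        M[f + 1, f] += g[f] / V[f + 1]
    return M


def _propagator(M: np.ndarray, dt: float, scheme: Scheme) -> np.ndarray:
    """One-step transition matrix B with c^{n+1} = B c^n."""
    n = M.shape[0]
    eye = np.eye(n)
    try:
        if scheme == "backward_euler":
            B = np.linalg.solve(eye - dt * M, eye)
        else:  # crank_nicolson
            B = np.linalg.solve(eye - 0.5 * dt * M, eye + 0.5 * dt * M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"linear solve failed: {exc}",
                             {"dt": dt, "n_cells": n}) from exc
    if not np.all(np.isfinite(B)):
        raise NumericalError("non-finite propagator (unstable linear solve)",
                             {"dt": dt, "n_cells": n})
    return B


def simulate_release(geometry: TranswellGeometry, drug: DrugProperties,
                     construct: ConstructSpec, config: SimulationConfig) -> SimulationResult:
    """Run the forward transport model and derive the release curve.

    Drug starts confined to the depot layer at ``initial_concentration`` and
    zero elsewhere; the system is closed (no-flux top and bottom). Since the
    semi-discrete system is linear and time-invariant, the solution is
    advanced between output times with cached powers of the one-step
    propagator, which is bitwise equivalent in exact arithmetic to stepping
    and keeps long horizons cheap.
    """
    if construct.form == "bolus":
        rel = abs(construct.effective_diffusivity - drug.diffusivity_media)
        _require(rel <= 1e-9 * drug.diffusivity_media,
                 "bolus construct must use the drug's media diffusivity")
    if construct.depot_volume is not None:
        _require(abs(construct.depot_volume - geometry.depot_volume)
                 <= 0.01 * geometry.depot_volume,
                 "construct.depot_volume inconsistent with geometry "
                 f"(got {construct.depot_volume:.4g}, geometry implies "
                 f"{geometry.depot_volume:.4g} m^3)")

    mesh = build_mesh(geometry, config)
    M = _diffusion_operator(mesh, geometry, drug, construct)
    B = _propagator(M, config.dt, config.scheme)

    c = np.where(mesh.domain == "depot", construct.initial_concentration, 0.0)
    c0_mass = mesh.mass(c)
    floor = NEGATIVE_FLOOR_MM * max(1.0, construct.initial_concentration)

    power_cache: dict[int, np.ndarray] = {}

    def advance(vec: np.ndarray, n_steps: int) -> np.ndarray:
        if n_steps == 0:
            return vec
        if n_steps not in power_cache:
            power_cache[n_steps] = np.linalg.matrix_power(B, n_steps)
        return power_cache[n_steps] @ vec

    times_h = np.asarray(config.output_times, float)
    fields: list[ConcentrationField] = []
    t_prev = 0.0
    for t_h in times_h:
        t_s = t_h * HOUR
        n_float = (t_s - t_prev) / config.dt
        n_steps = int(round(n_float))
        _require(abs(n_float - n_steps) < 1e-6,
                 f"output time {t_h} h is not an integer number of dt={config.dt}s steps")
        c = advance(c, n_steps)
        t_prev = t_s
        if not np.all(np.isfinite(c)):
            raise NumericalError("non-finite concentrations during time stepping",
                                 {"time_s": t_s})
        worst = float(c.min())
        if worst < -floor:
            raise NumericalError(
                f"negative concentration {worst:.3e} mM exceeds round-off floor",
                {"time_s": t_s, "min_concentration": worst})
        c = np.clip(c, 0.0, None)
        fields.append(ConcentrationField(mesh.z, c.copy(), t_s))

    well_sel = mesh.domain == "well_media"
    v_well = float(mesh.cell_volumes[well_sel].sum())
    well_conc = np.array([m.domain_mass(fld.node_concentrations, "well_media") / v_well
                          for m, fld in zip([mesh] * len(fields), fields)])
    if c0_mass <= 0:
        frac = np.zeros_like(well_conc)
    else:
        frac = np.array([mesh.domain_mass(fld.node_concentrations, "well_media") / c0_mass
                         for fld in fields])
    curve = ReleaseCurve(times=times_h, well_concentration=well_conc,
                         fraction_released=np.clip(frac, 0.0, 1.0))

    final_mass = mesh.mass(fields[-1].node_concentrations)
    diagnostics = {
        "initial_mass": c0_mass,
        "final_mass": final_mass,
        "mass_error_rel": abs(final_mass - c0_mass) / c0_mass if c0_mass > 0 else 0.0,
        "n_cells": mesh.n_cells,
        "scheme": config.scheme,
        "dt_s": config.dt,
    }
    logger.debug("simulate_release: %d cells, mass error %.2e",
                 mesh.n_cells, diagnostics["mass_error_rel"])
    return SimulationResult(curve=curve, fields=fields, mesh=mesh,
                            geometry=geometry, construct=construct,
                            diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def percent_release(result_or_curve: SimulationResult | ReleaseCurve,
                    construct: ConstructSpec,
                    geometry: TranswellGeometry) -> np.ndarray:
    """Fraction of the initially loaded drug that has reached the bottom well.

    Accepts either a full :class:`SimulationResult` (mass is integrated over
    the well cells of the mesh) or a bare :class:`ReleaseCurve` (well mass is
    reconstructed from the volume-averaged well concentration).
    """
    v_depot = construct.depot_volume if construct.depot_volume is not None \
        else geometry.depot_volume
    m0 = construct.initial_concentration * v_depot
    if m0 <= 0:
        raise ValidationError("initial depot drug amount is zero; percent release undefined")
    if isinstance(result_or_curve, SimulationResult):
        mesh = result_or_curve.mesh
        frac = np.array([mesh.domain_mass(f.node_concentrations, "well_media") / m0
                         for f in result_or_curve.fields])
    else:
        curve = result_or_curve
        frac = curve.well_concentration * geometry.well_volume / m0
    return np.clip(frac, 0.0, 1.0)


def cell_apparent_concentration(fields: Sequence[ConcentrationField]) -> np.ndarray:
    """Concentration time series at the well bottom where the cells reside.

    Returns the bottom-boundary (last) node concentration of each field.
    """
    if len(fields) == 0:
        raise ValidationError("cell_apparent_concentration requires at least one field")
    return np.array([float(f.node_concentrations[-1]) for f in fields])


def equilibrium_concentration(geometry: TranswellGeometry,
                              construct: ConstructSpec) -> float:
    """The t -> infinity uniform concentration of the closed system.

    C_eq = C0 * V_depot / (V_insert + V_well); the depot layer is part of the
    insert fluid volume.
    """
    v_depot = construct.depot_volume if construct.depot_volume is not None \
        else geometry.depot_volume
    return construct.initial_concentration * v_depot / (
        geometry.insert_volume + geometry.well_volume)


def time_to_fraction(geometry: TranswellGeometry, drug: DrugProperties,
                     construct: ConstructSpec, target_fraction: float,
                     *, dt: float = 10.0, nodes_depot: int = 20,
                     nodes_media: int = 40, scheme: Scheme = "backward_euler",
                     max_days: float = 30.0, resolution_h: float = 1.0) -> float | None:
    """First time (in days) at which cumulative fractional release reaches target.

    Scans the release curve on an hourly grid out to ``max_days``; returns
    ``None`` if the target is never reached (e.g. the closed-system
    equilibrium fraction V_well/V_total lies below the target).
    """
    _require(0 < target_fraction <= 1, "target_fraction must be in (0, 1]")
    n_out = int(round(max_days * 24 / resolution_h))
    times = tuple(np.linspace(0.0, max_days * 24.0, n_out + 1))
    config = SimulationConfig(dt=dt, t_end=max_days * DAY, output_times=times,
                              nodes_depot=nodes_depot, nodes_media=nodes_media,
                              scheme=scheme)
    result = simulate_release(geometry, drug, construct, config)
    frac = result.curve.fraction_released
    hit = np.nonzero(frac >= target_fraction)[0]
    if hit.size == 0:
        return None
    return float(result.curve.times[hit[0]] / 24.0)


# ---------------------------------------------------------------------------
# Standard geometries (catalog-typical transwell dimensions)
# ---------------------------------------------------------------------------

def default_geometry_24well(depot_volume: float = 50e-9,
                            membrane_permeability: float | None = None
                            ) -> TranswellGeometry:
    """24-well transwell: 0.33 cm^2 insert, 1.9 cm^2 well, 100/600 uL fluid."""
    a_ins, a_well = 0.33e-4, 1.9e-4
    v_ins, v_well = 100e-9, 600e-9
    return TranswellGeometry(
        insert_membrane_area=a_ins,
        insert_fluid_depth=v_ins / a_ins,
        well_cross_area=a_well,
        well_fluid_depth=v_well / a_well,
        depot_thickness=depot_volume / a_ins,
        plate_format="well24",
        membrane_permeability=membrane_permeability,
    )


def default_geometry_96well(depot_volume: float = 25e-9,
                            membrane_permeability: float | None = None
                            ) -> TranswellGeometry:
    """96-well transwell: 0.143 cm^2 insert, 0.32 cm^2 well, 75/235 uL fluid."""
    a_ins, a_well = 0.143e-4, 0.32e-4
    v_ins, v_well = 75e-9, 235e-9
    return TranswellGeometry(
        insert_membrane_area=a_ins,
        insert_fluid_depth=v_ins / a_ins,
        well_cross_area=a_well,
        well_fluid_depth=v_well / a_well,
        depot_thickness=depot_volume / a_ins,
        plate_format="well96",
        membrane_permeability=membrane_permeability,
    )


__all__ = [
    "TranswellGeometry", "DrugProperties", "ConstructSpec", "SimulationConfig",
    "ConcentrationField", "ReleaseCurve", "Mesh", "SimulationResult",
    "build_mesh", "simulate_release", "percent_release",
    "cell_apparent_concentration", "equilibrium_concentration",
    "time_to_fraction", "default_geometry_24well", "default_geometry_96well",
    "HOUR", "DAY", "replace",
]
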