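"""Seeded generators for every input the analysis pipeline consumes.

Three generators emulate the study's data streams so every stage is testable
without any download:

* noisy release curves produced by the forward transwell model at a known
  effective diffusivity, sampled at the assay schedule
  {0, 1, 2, 4, 12, 24, 48, 96} h (HPLC measurement error is emulated as 2%
  multiplicative Gaussian noise by default);
* confocal-style z-stacks of ~200 um alginate beads (diameter ~ Normal with
  5% CV) containing bright liposome spots at known ground-truth centroids,
  rendered as in-plane Gaussians on slices 50 um apart;
* replicate viability measurements drawn around the tabulated dose-response
  means, with the SEM-implied standard deviation (sd = sem * sqrt(n_exp),
  n_exp = 3 independent experiments).

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .release_model import (ConstructSpec, DrugProperties, ReleaseCurve,
                            SimulationConfig, TranswellGeometry,
                            default_geometry_24well, simulate_release, HOUR)
from .bead_imaging import CentroidSet, ZStack
from .viability_map import ViabilityTable

logger = logging.getLogger("depotsim")

ASSAY_TIMES_H = (0.0, 1.0, 2.0, 4.0, 12.0, 24.0, 48.0, 96.0)

DEFAULT_DRUG = DrugProperties(
    name="bupivacaine", diffusivity_media=1e-10, molar_mass=288.43,
    metadata={"diffusivity_printed_as": "1E-10 mol/m^3"})

DEFAULT_CONSTRUCT = ConstructSpec(
    form="liposome_alginate", initial_concentration=1.0,
    effective_diffusivity=8.5e-15, depot_volume=50e-9,
    metadata={"effective_diffusivity_printed_as": "8.5E-15 mol/m^3"})


# ---------------------------------------------------------------------------
# Release curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseGenSpec:
    """Recipe for a synthetic release curve from a known diffusivity."""

    true_diffusivity: float = 8.5e-15  # m^2/s
    geometry: TranswellGeometry = field(default_factory=default_geometry_24well)
    drug: DrugProperties = DEFAULT_DRUG
    construct: ConstructSpec = DEFAULT_CONSTRUCT
    noise_model: str = "multiplicative_gaussian"  # {none, additive_gaussian, multiplicative_gaussian}
    noise_scale: float = 0.02
    seed: int = 0
    sample_times: tuple[float, ...] = ASSAY_TIMES_H
    dt: float = 10.0
    nodes_depot: int = 20
    nodes_media: int = 40

    def __post_init__(self):
        if self.noise_model not in ("none", "additive_gaussian", "multiplicative_gaussian"):
            raise ValidationError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")
        if self.true_diffusivity <= 0:
            raise ValidationError("true_diffusivity must be > 0")


def generate_release_data(spec: ReleaseGenSpec) -> ReleaseCurve:
    """Forward-simulate at the true diffusivity, then apply measurement noise.

    With ``noise_model="none"`` the output is exactly the forward-model
    curve. Multiplicative noise scales each measured concentration by
    ``1 + noise_scale * N(0,1)``; additive noise adds
    ``noise_scale * max(conc) * N(0,1)``. Noisy concentrations are clipped at
    zero and the released fraction is recomputed from the noisy values to
    keep the curve internally consistent.
    """
    construct = replace(spec.construct, effective_diffusivity=spec.true_diffusivity)
    config = SimulationConfig(dt=spec.dt, t_end=spec.sample_times[-1] * HOUR,
                              output_times=spec.sample_times,
                              nodes_depot=spec.nodes_depot,
                              nodes_media=spec.nodes_media)
    result = simulate_release(spec.geometry, spec.drug, construct, config)
    if spec.noise_model == "none" or spec.noise_scale == 0:
        return result.curve

    rng = np.random.default_rng(spec.seed)
    conc = result.curve.well_concentration.copy()
    eps = rng.standard_normal(conc.size)
    if spec.noise_model == "multiplicative_gaussian":
        conc = conc * (1.0 + spec.noise_scale * eps)
    else:
        conc = conc + spec.noise_scale * conc.max() * eps
    conc = np.clip(conc, 0.0, None)

    v_depot = construct.depot_volume if construct.depot_volume is not None \
        else spec.geometry.depot_volume
    m0 = construct.initial_concentration * v_depot
    frac = np.clip(conc * spec.geometry.well_volume / m0, 0.0, 1.0)
    return ReleaseCurve(times=result.curve.times, well_concentration=conc,
                        fraction_released=frac)


# ---------------------------------------------------------------------------
# Bead z-stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadGenSpec:
    """Recipe for a synthetic bead z-stack with ground-truth spot centroids."""

    n_spots: int = 30
    bead_diameter_mean: float = 200.0  # um
    bead_diameter_cv: float = 0.05
    #: In-plane PSF sigma in pixels; sub-micron liposomes image as
    #: diffraction-limited spots, ~1 px at 2 um pixels.
    spot_sigma_px: float = 1.2
    spot_amplitude: float = 1.0
    background_level: float = 0.1
    noise_sd: float = 0.02
    pixel_size_xy: float = 1.0  # um
    image_size_px: int = 256
    z_spacing: float = 50.0  # um
    #: Optional in-plane exclusion radius (same slice). 0 = none: spot
    #: placement is then exactly CSR, which the uniformity test assumes.
    min_separation_px: float = 0.0
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self):
        if self.n_spots < 0:
            raise ValidationError("n_spots must be >= 0")
        if self.bead_diameter_cv < 0:
            raise ValidationError("bead_diameter_cv must be >= 0")
        if self.bead_diameter_mean <= 0 or self.pixel_size_xy <= 0 or self.z_spacing <= 0:
            raise ValidationError("physical sizes must be > 0")
        half_extent = self.image_size_px * self.pixel_size_xy / 2
        if self.bead_diameter_mean / 2 > half_extent:
            raise ValidationError("image field of view smaller than the bead")


def generate_bead_stack(spec: BeadGenSpec) -> tuple[ZStack, CentroidSet]:
    """Render one bead: sampled diameter, uniformly placed spots, noise.

    The bead is centred in the image; slice planes sit at multiples of
    ``z_spacing`` about the equator, covering |z| < radius. Spot centres are
    uniform in the bead sphere, snapped in z to the nearest plane (matching
    how the acquisition sees one liposome layer per slice). A nonzero
    ``min_separation_px`` resamples spots landing too close to an earlier
    spot in the same plane; the default keeps placement exactly CSR. The
    returned truth stores each spot at its rendered (x, y, plane-z) position
    in bead-centred um, plus the sampled bead radius.
    """
    rng = np.random.default_rng(spec.seed)
    diameter = rng.normal(spec.bead_diameter_mean,
                          spec.bead_diameter_cv * spec.bead_diameter_mean)
    diameter = max(diameter, 4 * spec.z_spacing / 2)  # guard absurd low tail
    radius = diameter / 2.0

    k_max = int(np.floor((radius - 1e-9) / spec.z_spacing))
    plane_z = np.arange(-k_max, k_max + 1) * spec.z_spacing  # bead-centred um
    n_px = spec.image_size_px
    center_px = (n_px - 1) / 2.0

    placed: list[tuple[float, float, int]] = []  # (col_px, row_px, plane index)
    truth = []
    attempts = 0
    while len(placed) < spec.n_spots:
        if attempts > spec.max_retries + spec.n_spots:
            raise ValidationError(
                "could not place all spots with the requested separation")
        attempts += 1
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r = radius * rng.random() ** (1.0 / 3.0)
        x, y, z = v * r
        k = int(np.argmin(np.abs(plane_z - z)))
        col = center_px + x / spec.pixel_size_xy
        row = center_px + y / spec.pixel_size_xy
        margin = 3 * spec.spot_sigma_px + 1
        if not (margin <= col <= n_px - 1 - margin and margin <= row <= n_px - 1 - margin):
            continue
        if spec.min_separation_px > 0 and any(
                k == k0 and np.hypot(col - c0, row - r0) < spec.min_separation_px
                for c0, r0, k0 in placed):
            continue
        placed.append((col, row, k))
        truth.append([(col - center_px) * spec.pixel_size_xy,
                      (row - center_px) * spec.pixel_size_xy,
                      plane_z[k]])

    voxels = np.full((plane_z.size, n_px, n_px), spec.background_level, float)
    for col, row, k in placed:
        lo_r = max(int(row - 4 * spec.spot_sigma_px), 0)
        hi_r = min(int(row + 4 * spec.spot_sigma_px) + 2, n_px)
        lo_c = max(int(col - 4 * spec.spot_sigma_px), 0)
        hi_c = min(int(col + 4 * spec.spot_sigma_px) + 2, n_px)
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        voxels[k, lo_r:hi_r, lo_c:hi_c] += spec.spot_amplitude * np.exp(
            -((rr - row) ** 2 + (cc - col) ** 2) / (2 * spec.spot_sigma_px ** 2))
    # detector saturation: co-located fluorophores clip at full scale rather
    # than summing, which keeps per-slice normalisation stable
    np.minimum(voxels, spec.background_level + spec.spot_amplitude, out=voxels)
    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    meta = {
        "bead_center_um": [center_px * spec.pixel_size_xy,
                           center_px * spec.pixel_size_xy,
                           (plane_z.size - 1) / 2.0 * spec.z_spacing],
        "bead_diameter_um": float(diameter),
        "seed": spec.seed,
    }
    stack = ZStack(voxels=voxels, pixel_size_xy=spec.pixel_size_xy,
                   z_spacing=spec.z_spacing, bead_diameter_nominal=float(diameter),
                   metadata=meta)
    truth_set = CentroidSet(points=np.array(truth, float).reshape(-1, 3),
                            bead_radius=radius,
                            tolerance=max(spec.pixel_size_xy, spec.z_spacing))
    return stack, truth_set


def sample_bead_diameters(spec: BeadGenSpec, n_beads: int) -> np.ndarray:
    """Sampled diameters of ``n_beads`` beads generated one after another.

    Runs the full stack generator per bead (seeds ``seed .. seed+n-1``) and
    collects the sampled diameter each stack records.
    """
    out = np.empty(n_beads)
    for i in range(n_beads):
        stack, _ = generate_bead_stack(replace(spec, seed=spec.seed + i))
        out[i] = stack.metadata["bead_diameter_um"]
    return out


# ---------------------------------------------------------------------------
# Viability replicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViabilityGenSpec:
    """Recipe for replicate viability measurements around tabulated means."""

    table: ViabilityTable
    n_replicates: int = 4
    n_experiments: int = 3  # number of experiments behind each tabulated SEM
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.n_experiments < 1:
            raise ValidationError("n_experiments must be >= 1")


def generate_viability_data(spec: ViabilityGenSpec) -> pd.DataFrame:
    """Draw replicate viabilities ~ Normal(mean, sem * sqrt(n_experiments)).

    Returns a tidy frame with columns ``concentration_mM``, ``exposure_h``,
    ``replicate``, ``viability``. The implied per-measurement standard
    deviation recovers the tabulated SEM when averaged over
    ``n_experiments`` observations.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    t_grid = spec.table.exposure_times
    c_grid = spec.table.concentrations
    for i, t in enumerate(t_grid):
        for j, c in enumerate(c_grid):
            mean = spec.table.mean_viability[i, j]
            sd = spec.table.sem[i, j] * np.sqrt(spec.n_experiments)
            vals = rng.normal(mean, sd, spec.n_replicates)
            for r, v in enumerate(vals):
                rows.append({"concentration_mM": c, "exposure_h": t,
                             "replicate": r, "viability": float(v)})
    return pd.DataFrame(rows)


__all__ = [
    "ReleaseGenSpec", "BeadGenSpec", "ViabilityGenSpec",
    "generate_release_data", "generate_bead_stack", "generate_viability_data",
    "sample_bead_diameters", "ASSAY_TIMES_H", "DEFAULT_DRUG", "DEFAULT_CONSTRUCT",
]
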