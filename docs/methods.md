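# Methods

This note documents the models, numerical choices and design decisions
behind `depotsim`, and what the synthetic-data generators do and do not
emulate.

## Transport model

The transwell system is closed: a drug depot (a bolus solution, a liposome
suspension, or a liposome-alginate composite) sits at the top of the insert;
drug diffuses through the insert medium, across the membrane, and into the
bottom well. We model pure Fickian diffusion. A static culture plate has no
forcing, so the steady incompressible flow field is identically zero and a
convection term would contribute nothing; buoyancy-driven micro-convection
and plate handling are deliberately ignored. A prescribed membrane
permeability (m/s) is available as a hook for membrane-limited systems; by
default the membrane is freely permeable, since no membrane resistance is
specified for the assay.

The liposome-alginate composite is treated as a single homogeneous layer
with one effective diffusivity. This is a phase model: drug-alginate and
drug-lipid binding, the discrete liposome sub-structure, and cellular uptake
are all outside it. The practical consequence, visible when the model is
compared with early-time release data, is that the homogeneous model
releases faster than reality before ~24 h; the effective diffusivity is an
asymptotic (late-time) transport summary, not an early-time one.

### Units

The two diffusivities are stored as m²/s. The source report prints both with
concentration units (mol/m³), which cannot be diffusivities; 1e-10 m²/s is a
physically plausible free-solution diffusivity for a ~288 g/mol amphiphile,
so both printed numbers are interpreted as m²/s and the original printed
strings are preserved in the packaged parameter file's metadata.
Concentration is carried in mM throughout, which is numerically identical to
mol/m³, so no conversion ambiguity exists at the I/O boundary.

### Geometry

The 3D well is reduced to a 1D axial finite-volume mesh with a
cross-sectional-area jump at the insert-well interface; radial gradients are
neglected because transwell transport is predominantly axial. Because the
scheme is finite-volume, the discrete mass bookkeeping is exact: total drug
amount is invariant to round-off at every step (the tests require 0.1% and
observe ~1e-13 relative drift).

The assay plate dimensions are not part of the release data, so
catalog-typical transwell dimensions are used and are fully overridable:

| parameter | 24-well | 96-well |
|---|---|---|
| insert membrane area | 0.33 cm² | 0.143 cm² |
| well cross-area | 1.9 cm² | 0.32 cm² |
| insert fluid volume | 100 μL | 75 μL |
| well fluid volume | 600 μL | 235 μL |

The depot layer volume is likewise unstated; the packaged parameter file
uses a 50 μL alginate-liposome layer (half the insert fluid), a typical
bead-slurry aliquot for a 24-well insert. The equilibrium fraction of drug
in the well of a closed 24-well system is V_well/V_total = 600/700 ≈ 0.857,
which is why 95% cumulative release is never reached: sustained-release
claims are evaluated against the release trajectory, with a 30-day cap.

### Discretisation

* Implicit time stepping at dt = 10 s, matching the assay model's stated
  step; backward Euler by default (unconditionally stable, positivity
  preserving), Crank-Nicolson optional.
* Because the semi-discrete operator is linear and time-invariant, the
  solver advances between output times with cached integer powers of the
  one-step propagator — algebraically identical to stepping, and cheap
  enough (milliseconds for a 96 h run on a 60-cell mesh) that the
  diffusivity fit and 30-day horizons cost nothing.
* The depot cells are geometrically graded (default ratio 1.35 between
  neighbours, finest at the depot-media interface). The release of a slow
  depot is controlled by a boundary layer of width ~sqrt(D_eff t) — ~50 μm
  at 96 h for D_eff ~ 1e-14 m²/s — which a uniform 20-cell depot mesh
  cannot resolve. With grading, doubling all node counts changes the 96 h
  released fraction by ~0.1%.
* Default resolution 20 depot + 40 media cells; the media cells are split
  between insert and well regions in proportion to their depths.
* Face conductances use harmonic averaging of the piecewise diffusivity
  (flux continuity at material interfaces); a finite membrane permeability
  enters as a series resistance at the membrane face.
* Concentrations more negative than 1e-12 mM (scaled by the initial
  concentration) raise a numerical error; smaller negatives are round-off
  and are clipped to zero.

One caveat the tests document: under quiescent diffusion the 96-well bolus
system approaches insert/well equilibrium over tens of hours, not "a few".
Fast equilibration in small-format plates requires convective mixing, which
this model deliberately omits; the geometry dependence itself (96-well
equilibrates within the assay window, larger formats do not) is reproduced.

## Diffusivity estimation

The fit minimises the unweighted sum of squared differences between
simulated and observed well concentrations at the observed time points
(t = 0 contributes zero and is retained for bookkeeping). Design choices:

* Fit quantity: well concentration rather than percent release — the two
  are proportional for a fixed geometry, and concentration is what the
  assay measures. Points are unweighted; note that for long-release design
  questions the later time points carry the clinically relevant signal.
* Search on log10(D), default bounds [1e-18, 1e-10] m²/s: release varies
  over orders of magnitude in D and is monotone in it, making SSE(log D)
  unimodal for monotone-release data (asserted empirically on a probe grid
  in the tests).
* A 9-point log-grid scan brackets the basin, then bounded scalar
  minimisation refines to 1e-4 in log10(D) (~0.02% in D). A grid argmin at
  either end pins the estimate to that bound with `converged=False`.
* Observed data must be sampled at the simulation output times; time grids
  differing by more than 1 s raise an alignment error. No silent
  interpolation: resampling would bias the SSE.
* A finite-difference curvature of the SSE minimum yields an approximate
  standard error of log10(D̂); it is a local quadratic approximation, not a
  posterior.

## Viability mapping and safety logic

The packaged dose-response table (doses 0, 0.01, 0.1, 0.5, 1 mM; exposures
24 h, 48 h; mean % of basal control ± SEM) ships verbatim as CSV. The
"62 ± 35" cell (0.5 mM, 48 h) lacks a % sign on the SEM and is very likely a
typographical artefact of "62 ± 3%"; it is stored as printed (mean 62,
SEM 35) and flagged suspect in metadata rather than silently repaired —
only the mean enters any downstream logic.

Interpolation between doses is linear in log10(dose) (pharmacological
convention), with the 0 mM control handled on a linear segment to the
smallest positive dose; values above the tabulated maximum raise an error
rather than extrapolate. Only two exposure durations exist, so off-grid
exposures use the nearest tabulated time with a warning. The safety ceiling
is the largest *tabulated* dose meeting the viability floor (default 90%,
yielding 0.1 mM at 48 h) — deliberately not an interpolated crossing, since
the floor convention is defined against tested doses.

`classify_release_safety` screens any concentration time series (the
simulated well or cell-apparent series) against the ceiling: the profile is
safe iff it never exceeds the threshold, and the first exceedance time is
reported otherwise.

Group comparison reimplements one-way ANOVA from sums of squares with
Fisher LSD pairwise t statistics on the pooled within-group mean square
(α = 0.05, no multiplicity adjustment — that is the LSD procedure). The
tests cross-check it against an independent ANOVA implementation and a
permutation reference.

## Bead imaging

Z-stacks are segmented slice by slice: the 50 μm z-spacing was chosen to see
each liposome layer in exactly one section, so no 3D merging across slices
is performed and each region's z is its slice plane. Per slice: min-max
normalisation to [0, 1] (or percentile-clipped normalisation for hot-pixel
robustness), a white-pixel threshold at 0.5 of the normalised range (the
original pipeline's threshold value is unknown; 0.5 is exposed as a
parameter), 8-connected component labelling, and a 2-pixel minimum region
size. A slice whose raw dynamic range is below 20% of the stack's range is
treated as empty: per-slice normalisation would otherwise stretch pure
background noise into spurious foreground. Both the normalisation and the
range guard are ratios, so segmentation is invariant to affine intensity
rescaling of the raw stack.

Centroids are unweighted (binary-mask) voxel centroids converted to μm; the
bead origin comes from acquisition metadata when available, otherwise from
the centroid of the stacked per-slice convex hull of the foreground (the
hull fills the space between spots, tracking the bead body). For synthetic
round-trips the generator-declared centre is used — a hull estimate from
n spots carries O(R/√n) error that would dominate sub-voxel comparisons.

Spatial uniformity is assessed as the mean nearest-neighbour distance
against a Monte-Carlo null of the same number of points uniform in a sphere
of the bead radius, with a rank-based two-sided p-value (+1 correction).
This NN/CSR formulation is a stated interpretation of "between-centroid"
distance analysis, not a reconstruction of the original unspecified
statistic. One subtlety matters in practice: measured centroids carry the z
of their slice plane, so the null must be snapped to the same planes
(`z_planes` argument) or uniform beads would be misread as z-clustered; the
continuous null remains the default for genuinely continuous coordinates
and is what the type-I-error calibration tests exercise.

## Synthetic data generators

All generators are pure functions of their spec, seed included.

* **Release curves** — the forward model at a known diffusivity plus
  measurement noise. The assay's measurement error is unreported; the
  default is 2% multiplicative Gaussian noise, a typical HPLC
  repeatability figure. Released fractions are recomputed from the noisy
  concentrations so each curve stays internally consistent.
* **Bead stacks** — bead diameter ~ Normal(200 μm, CV 5%) (the population
  spread statistic behind "± 5%" is taken as a coefficient of variation);
  spots uniform in the bead sphere (exact CSR), rendered as in-plane
  Gaussian spots (σ = 1.2 px at 1 μm pixels — sub-micron liposomes are
  diffraction-limited) on slices 50 μm apart, z snapped to the nearest
  plane as the acquisition would; detector saturation clips co-located
  fluorophores at full scale; Gaussian read noise (σ = 0.02 of full scale).
  Not emulated: PSF blur across z, bead autofluorescence gradients,
  refractive-index attenuation with depth, bead truncation at the image
  border. Segmentation results on real stacks will degrade where those
  effects are strong; the round-trip tests therefore validate the
  pipeline's geometry and bookkeeping, not its robustness to optical
  artefacts.
* **Viability replicates** — Normal(mean, SEM·√n) per table cell with
  n = 3 independent experiments (the tabulated SEMs derive from 3-4);
  replicate means converge to the table means.

Passing tests on these generators demonstrate internal consistency
(round-trip identifiability, calibration of the declared noise levels,
nominal test sizes), not agreement with any particular laboratory's data.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the forward model at the default
60-cell mesh and dt = 10 s; the fit searches 8 decades of D; the CSR
calibration uses 200 uniform draws × 199 Monte-Carlo permutations; bead
round-trips use 3-5 stacks of 30 spots; the bead-population check samples
500 beads; the ANOVA/permutation comparison uses 3 groups × 8 replicates ×
2000 permutations. These sizes give Monte-Carlo margins comfortably inside
the asserted tolerances.

## Known limitations

* No convection, binding, degradation or cellular uptake: the model is a
  late-time transport summary (see above).
* The effective diffusivity is identified from a single release curve in a
  fixed geometry; it is only transferable to other geometries under the
  same homogeneous-layer assumption.
* Only two tabulated exposure durations; viability at intermediate
  exposures is a nearest-grid lookup, not a kinetic model of cell death.
* Per-bead spatial statistics only; no batch-level pooling across beads.
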