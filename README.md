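# depotsim

Transwell release modelling and safety analysis for liposome-alginate local
anesthetic depots.

## The problem

Local anesthetics (LAs) such as bupivacaine are co-administered with
mesenchymal stromal cell (MSC) therapies, but a bolus LA dose is cytotoxic:
MSC viability falls steeply with concentration and exposure time. A
sustained-release depot — bupivacaine-loaded liposomes embedded in an
alginate microbead matrix — can keep the concentration the cells actually
see below a safe ceiling while still delivering analgesia for several days.

`depotsim` is the computational side of that design problem, for
pharmaceutical scientists and biomedical engineers working with transwell
release assays:

1. **Forward transport model** (`release_model`) — 1D axial Fickian
   diffusion of drug from a depot layer at the top of a transwell insert,
   through the insert medium and permeable membrane, into the bottom well
   where cells reside. The depot is one homogeneous layer with a single
   effective diffusivity `D_eff`; the concentration field obeys

       ∂c/∂t = ∂/∂z ( D(z) ∂c/∂z ),   D(z) = D_eff in the depot,
                                       D(z) = D_media elsewhere,

   with no-flux boundaries (closed system) and a cross-sectional-area jump
   at the insert-well interface. A finite-volume discretisation conserves
   drug mass to round-off; implicit time stepping (backward Euler, dt = 10 s)
   is unconditionally stable.
2. **Effective-diffusivity estimation** (`diffusivity_fit`) — find
   `D̂ = argmin_D Σ_i (c_obs(t_i) − c_model(t_i; D))²` over a log-scale
   search, at the assay's sampling times {0, 1, 2, 4, 12, 24, 48, 96} h.
3. **Viability safety mapping** (`viability_map`) — the packaged MSC
   dose-response table (mean viability % ± SEM on a 0–1 mM × 24/48 h grid),
   log-dose interpolation, the largest dose meeting a viability floor
   (90% by default, giving the 0.1 mM ceiling), screening of simulated
   release profiles against that ceiling, and one-way ANOVA with Fisher LSD
   post-hoc comparisons for replicate viability measurements.
4. **Bead imaging** (`bead_imaging`) — per-slice normalisation,
   white-pixel thresholding and 2D connected-component segmentation of
   confocal z-stacks of ~200 μm alginate beads taken at 50 μm intervals;
   3D centroid extraction; and a Monte-Carlo complete-spatial-randomness
   test of liposome distribution based on mean nearest-neighbour distance.
5. **Synthetic data** (`synthetic_data`) — seeded generators for noisy
   release curves from a known diffusivity, bead z-stacks with ground-truth
   spot centroids, and replicate viability datasets, so the whole pipeline
   is testable end to end without any experimental download.

## Worked example

```python
import depotsim as ds

# packaged parameters: 1 mM bupivacaine liposome-alginate depot,
# D_eff = 8.5e-15 m^2/s, D_media = 1e-10 m^2/s, 24-well transwell
bundle = ds.packaged_parameters()
result = ds.simulate_release(bundle.geometry, bundle.drug,
                             bundle.construct, bundle.config)
cell = ds.cell_apparent_concentration(result.fields)
print("fraction released at 96 h:", round(result.curve.fraction_released[-1], 4))
print("max cell-apparent concentration (mM):", round(cell.max(), 5))

table = ds.ViabilityTable.packaged()
ceiling = ds.max_safe_concentration(table, viability_floor=90.0, exposure=48.0)
report = ds.classify_release_safety((result.curve.times, cell), threshold=ceiling)
print("safety ceiling (mM):", ceiling, "| construct safe:", report.safe)
```

prints

```
fraction released at 96 h: 0.0361
max cell-apparent concentration (mM): 0.00293
safety ceiling (mM): 0.1 | construct safe: True
```

i.e. over 96 hours the 1 mM depot releases only ~3.6% of its load into the
bottom well, the cells never see more than ~0.003 mM — thirty-fold below the
0.1 mM dose that still preserves 90% MSC viability at 48 h — and the
release profile is classified safe.

The same operations are available from the shell:

```sh
depotsim simulate --params params.yaml --out curve.csv
depotsim fit --params params.yaml --observed curve.csv --out fit.json
depotsim safety --curve curve.csv --floor 90 --exposure 48
depotsim beads --stack bead.tif --meta bead.json --threshold 0.5 --mc 999 --seed 7
depotsim synth release --seed 1 --out synthetic.csv
```

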