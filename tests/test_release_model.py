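"""Transwell solver: mesh construction, transport physics, derived quantities."""

import numpy as np
import pytest

import depotsim as ds
from depotsim.release_model import HOUR


def two_compartment_setup(permeability=1e-7, depth=1e-3, area=1e-4):
    """Membrane-limited exchange between two well-mixed compartments.

    Internal diffusion is fast (D = 1e-7 m^2/s, mixing time ~10 s) so the
    membrane permeability controls the kinetics and the closed-form
    two-compartment ODE solution is an independent oracle.
    """
    geom = ds.TranswellGeometry(
        insert_membrane_area=area, insert_fluid_depth=depth,
        well_cross_area=area, well_fluid_depth=depth, depot_thickness=depth,
        membrane_permeability=permeability)
    drug = ds.DrugProperties(name="tracer", diffusivity_media=1e-7)
    con = ds.ConstructSpec(form="liposome_alginate", initial_concentration=1.0,
                           effective_diffusivity=1e-7)
    cfg = ds.SimulationConfig(dt=10, t_end=8 * HOUR,
                              output_times=(0.5, 1, 2, 4, 8),
                              nodes_depot=3, nodes_media=3, depot_grading=1.0)
    return geom, drug, con, cfg


class TestBuildMesh:
    def test_equal_area_depot_fills_insert_gives_two_domains(self):
        geom = ds.TranswellGeometry(
            insert_membrane_area=1e-4, insert_fluid_depth=1e-3,
            well_cross_area=1e-4, well_fluid_depth=1e-3, depot_thickness=1e-3)
        cfg = ds.SimulationConfig(nodes_depot=3, nodes_media=3, depot_grading=1.0)
        mesh = ds.build_mesh(geom, cfg)
        assert mesh.n_cells == 6
        assert np.all(mesh.area == 1e-4)
        assert set(mesh.domain) == {"depot", "well_media"}
        assert np.allclose(mesh.dz, 1e-3 / 3)

    def test_24well_default_mesh_matches_hand_computed_positions(self, paper_bundle):
        """60-cell mesh: graded depot, 13+27 media cells, area step at membrane."""
        g, cfg = paper_bundle.geometry, paper_bundle.config
        mesh = ds.build_mesh(g, cfg)
        assert mesh.n_cells == 60

        # depot: geometric widths, ratio 1.35, finest at the interface
        L_d = g.depot_thickness
        r = cfg.depot_grading
        w_min = L_d * (r - 1) / (r ** 20 - 1)
        widths = [w_min * r ** (19 - k) for k in range(20)]
        # media: split 40 nodes by depth -> 13 insert cells, 27 well cells
        L_im = g.insert_fluid_depth - g.depot_thickness
        L_w = g.well_fluid_depth
        assert round(40 * L_im / (L_im + L_w)) == 13
        widths += [L_im / 13] * 13 + [L_w / 27] * 27
        edges = np.concatenate([[0], np.cumsum(widths)])
        centers = 0.5 * (edges[:-1] + edges[1:])
        np.testing.assert_allclose(mesh.z, centers, rtol=1e-12)

        # cross-section area steps only at the insert-well transition
        assert np.all(mesh.area[:33] == g.insert_membrane_area)
        assert np.all(mesh.area[33:] == g.well_cross_area)
        assert mesh.membrane_face == 32
        assert list(mesh.domain).count("depot") == 20

    def test_depot_filling_insert_drops_insert_media_domain(self):
        geom = ds.TranswellGeometry(
            insert_membrane_area=3.3e-5, insert_fluid_depth=3e-3,
            well_cross_area=1.9e-4, well_fluid_depth=3.2e-3, depot_thickness=3e-3)
        mesh = ds.build_mesh(geom, ds.SimulationConfig())
        assert "insert_media" not in mesh.domain
        assert list(mesh.domain).count("well_media") == 40

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ds.ValidationError, match="well_fluid_depth"):
            ds.TranswellGeometry(insert_membrane_area=1e-4, insert_fluid_depth=1e-3,
                                 well_cross_area=1e-4, well_fluid_depth=-1,
                                 depot_thickness=1e-3)
        with pytest.raises(ds.ValidationError, match="depot_thickness"):
            ds.TranswellGeometry(insert_membrane_area=1e-4, insert_fluid_depth=1e-3,
                                 well_cross_area=1e-4, well_fluid_depth=1e-3,
                                 depot_thickness=2e-3)


class TestSimulateRelease:
    def test_no_transport_limit(self, paper_bundle):
        b = paper_bundle
        frozen = ds.ConstructSpec(form="liposome_alginate", initial_concentration=1.0,
                                  effective_diffusivity=1e-25)
        res = ds.simulate_release(b.geometry, b.drug, frozen, b.config)
        assert np.all(res.curve.fraction_released < 1e-6)

    def test_mass_conserved_at_every_output(self, paper_run):
        m0 = paper_run.diagnostics["initial_mass"]
        for fld in paper_run.fields:
            m = paper_run.mesh.mass(fld.node_concentrations)
            assert abs(m - m0) / m0 < 1e-3

    def test_well_mass_monotone_nondecreasing(self, paper_run):
        well = [paper_run.mesh.domain_mass(f.node_concentrations, "well_media")
                for f in paper_run.fields]
        assert np.all(np.diff(well) >= -1e-15)

    def test_release_ordered_in_effective_diffusivity(self, paper_bundle):
        b = paper_bundle
        fracs = []
        for d in (1e-15, 1e-14):
            con = ds.ConstructSpec(form="liposome_alginate",
                                   initial_concentration=1.0,
                                   effective_diffusivity=d)
            fracs.append(ds.simulate_release(
                b.geometry, b.drug, con, b.config).curve.fraction_released)
        assert np.all(fracs[0] <= fracs[1] + 1e-12)

    def test_mesh_refinement_changes_96h_release_below_1pct(self, paper_bundle,
                                                            paper_run):
        b = paper_bundle
        fine = ds.SimulationConfig(output_times=b.config.output_times,
                                   nodes_depot=2 * b.config.nodes_depot,
                                   nodes_media=2 * b.config.nodes_media)
        res2 = ds.simulate_release(b.geometry, b.drug, b.construct, fine)
        f1 = paper_run.curve.fraction_released[-1]
        f2 = res2.curve.fraction_released[-1]
        assert abs(f2 - f1) / f1 < 0.01

    def test_equilibrium_limit(self):
        """With fast diffusivities everywhere, all nodes approach C_eq."""
        geom = ds.default_geometry_24well()
        drug = ds.DrugProperties(name="fast", diffusivity_media=1e-9)
        con = ds.ConstructSpec(form="liposome_alginate", initial_concentration=1.0,
                               effective_diffusivity=1e-9)
        cfg = ds.SimulationConfig(dt=60, t_end=96 * HOUR, output_times=(96.0,))
        res = ds.simulate_release(geom, drug, con, cfg)
        c_eq = ds.equilibrium_concentration(geom, con)
        np.testing.assert_allclose(res.fields[-1].node_concentrations, c_eq,
                                   rtol=0.01)

    def test_two_compartment_oracle_agreement(self):
        """Coarse solver vs closed-form membrane-exchange ODE, within 5%."""
        geom, drug, con, cfg = two_compartment_setup()
        res = ds.simulate_release(geom, drug, con, cfg)
        V = geom.insert_volume
        k = geom.membrane_permeability * geom.insert_membrane_area * 2 / V
        t = np.array(cfg.output_times) * HOUR
        oracle_well = 0.5 * (1 - np.exp(-k * t))
        np.testing.assert_allclose(res.curve.well_concentration, oracle_well,
                                   rtol=0.05)
        cell = ds.cell_apparent_concentration(res.fields)
        np.testing.assert_allclose(cell, oracle_well, rtol=0.05)

    def test_96well_bolus_approaches_equilibrium_fastest(self, paper_bundle):
        """The 96-well bolus nears well/insert equilibrium within the run.

        Under quiescent diffusion the bolus system covers >85% of the gap to
        equilibrium by 96 h and is monotone, while the liposome-alginate
        construct in the same geometry stays far from equilibrium -- the
        geometry dependence the transwell model exists to capture.
        """
        g96 = ds.default_geometry_96well()
        drug = paper_bundle.drug
        bolus = ds.ConstructSpec(form="bolus", initial_concentration=1.0,
                                 effective_diffusivity=drug.diffusivity_media)
        cfg = ds.SimulationConfig(dt=60, t_end=96 * HOUR,
                                  output_times=(1, 2, 4, 12, 24, 48, 96))
        res = ds.simulate_release(g96, drug, bolus, cfg)
        c_eq = ds.equilibrium_concentration(g96, bolus)
        ratio = res.curve.well_concentration / c_eq
        assert np.all(np.diff(ratio) > 0)
        assert ratio[-1] > 0.85
        slow = ds.ConstructSpec(form="liposome_alginate", initial_concentration=1.0,
                                effective_diffusivity=8.5e-15)
        res_slow = ds.simulate_release(g96, drug, slow, cfg)
        assert res_slow.curve.well_concentration[-1] < 0.1 * c_eq

    def test_bolus_must_use_media_diffusivity(self, paper_bundle):
        b = paper_bundle
        bad = ds.ConstructSpec(form="bolus", initial_concentration=1.0,
                               effective_diffusivity=5e-12)
        with pytest.raises(ds.ValidationError, match="bolus"):
            ds.simulate_release(b.geometry, b.drug, bad, b.config)

    def test_crank_nicolson_matches_backward_euler(self, paper_bundle, paper_run):
        b = paper_bundle
        cfg = ds.SimulationConfig(output_times=b.config.output_times,
                                  scheme="crank_nicolson")
        res = ds.simulate_release(b.geometry, b.drug, b.construct, cfg)
        np.testing.assert_allclose(res.curve.well_concentration[1:],
                                   paper_run.curve.well_concentration[1:],
                                   rtol=0.02)


class TestDerivedQuantities:
    def test_percent_release_zero_before_any_transport(self, paper_bundle):
        b = paper_bundle
        cfg = ds.SimulationConfig(output_times=(0.0,), t_end=10.0)
        res = ds.simulate_release(b.geometry, b.drug, b.construct, cfg)
        assert ds.percent_release(res, b.construct, b.geometry)[0] == 0.0

    def test_percent_release_equilibrated_partition(self):
        """Fully mixed closed system: fraction = V_well / V_total."""
        geom = ds.default_geometry_24well()
        drug = ds.DrugProperties(name="fast", diffusivity_media=1e-9)
        con = ds.ConstructSpec(form="liposome_alginate", initial_concentration=1.0,
                               effective_diffusivity=1e-9)
        cfg = ds.SimulationConfig(dt=60, t_end=96 * HOUR, output_times=(96.0,))
        res = ds.simulate_release(geom, drug, con, cfg)
        expected = geom.well_volume / (geom.insert_volume + geom.well_volume)
        assert ds.percent_release(res, con, geom)[-1] == pytest.approx(expected,
                                                                       rel=0.01)

    def test_percent_release_field_and_curve_routes_agree(self, paper_bundle,
                                                          paper_run):
        b = paper_bundle
        from_fields = ds.percent_release(paper_run, b.construct, b.geometry)
        from_curve = ds.percent_release(paper_run.curve, b.construct, b.geometry)
        np.testing.assert_allclose(from_fields, from_curve, rtol=1e-9, atol=1e-15)

    def test_percent_release_undefined_for_zero_loading(self, paper_bundle):
        b = paper_bundle
        empty = ds.ConstructSpec(form="liposome_alginate", initial_concentration=0.0,
                                 effective_diffusivity=8.5e-15)
        with pytest.raises(ds.ValidationError, match="undefined"):
            ds.percent_release(ds.simulate_release(b.geometry, b.drug, empty,
                                                   b.config), empty, b.geometry)

    def test_cell_apparent_uniform_and_empty(self):
        fld = ds.ConcentrationField(node_positions=np.array([0.0, 1e-3, 2e-3]),
                                    node_concentrations=np.full(3, 0.05),
                                    time=0.0)
        assert ds.cell_apparent_concentration([fld])[0] == 0.05
        with pytest.raises(ds.ValidationError):
            ds.cell_apparent_concentration([])

    def test_equilibrium_concentration_arithmetic(self, paper_bundle):
        b = paper_bundle
        # 1 mM * 50 uL / (100 uL + 600 uL) = 1/14 mM
        assert ds.equilibrium_concentration(b.geometry, b.construct) == \
            pytest.approx(50.0 / 700.0, rel=1e-6)
        zero = ds.ConstructSpec(form="liposome_alginate", initial_concentration=0.0,
                                effective_diffusivity=1e-15)
        assert ds.equilibrium_concentration(b.geometry, zero) == 0.0

    def test_time_to_fraction_never_reaches_95pct(self, paper_bundle):
        """Closed transwell equilibrium fraction is V_well/V_total = 6/7 < 0.95."""
        b = paper_bundle
        days = ds.time_to_fraction(b.geometry, b.drug, b.construct, 0.95,
                                   max_days=5.0)
        assert days is None
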