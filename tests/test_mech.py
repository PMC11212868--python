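"""Finite-element mechanics: mesh, solver, scenarios, instability logic."""
import numpy as np
import pytest

from cardionuc.errors import GeometryError
from cardionuc.mech import (ActiveState, MechGeometry, MechMaterials,
                            build_mesh, build_model, detect_tip_instability,
                            probe_stresses, run_scenario, solve_ramp,
                            sweep_enrichment)
from cardionuc.mech.mesh import analytic_region_volumes, region_volumes
from cardionuc.mech.model import solve_ramp as _solve


@pytest.fixture(scope="module")
def wt_solution():
    return run_scenario("WT")


@pytest.fixture(scope="module")
def scenario_solutions(wt_solution):
    return {
        "WT": wt_solution,
        "LMNA_mut": run_scenario("LMNA_mut"),
        "csDNKASH": run_scenario("csDNKASH"),
        "LMNA_mut_csDNKASH": run_scenario("LMNA_mut_csDNKASH"),
    }


class TestMesh:
    def test_region_volumes_match_analytic(self):
        g = MechGeometry()
        mesh = build_mesh(g)
        vols = region_volumes(mesh)
        exact = analytic_region_volumes(g)
        for name in vols:
            assert vols[name] == pytest.approx(exact[name], rel=0.01)

    def test_refinement_improves_volumes(self):
        g = MechGeometry()
        exact = analytic_region_volumes(g)
        err = {}
        for refine in (1.0, 2.0):
            vols = region_volumes(build_mesh(g, refine=refine))
            err[refine] = sum(abs(vols[n] - exact[n]) / exact[n] for n in vols)
        assert err[2.0] < err[1.0]

    def test_thick_lamina_rejected(self):
        with pytest.raises(GeometryError):
            MechGeometry(lamina_thickness=1.0).validate()

    def test_cage_must_contain_nucleus(self):
        with pytest.raises(GeometryError):
            MechGeometry(cage_semi_axes=(3.0, 6.8)).validate()


class TestSolver:
    def test_zero_load_is_exactly_undeformed(self):
        model = build_model(active=ActiveState(rho0=0.0, sigma_mt=0.0,
                                               polarization="none", n_steps=2))
        sol = solve_ramp(model)
        assert np.max(np.abs(sol.U)) == 0.0
        assert sol.nuclear_aspect_ratio == pytest.approx(1.0, abs=1e-12)
        for v in probe_stresses(sol).values():
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_small_load_matches_constrained_cylinder_closed_form(self):
        """Homogeneous cell, no cage stress, tiny isotropic contractility.

        Closed form (linear elasticity, fixed ends, free lateral surface):
        uniform radial strain eps_r = -rho0 / (2 (lambda + mu)).
        """
        E, nu = 5.0, 0.3
        mats = MechMaterials(
            moduli={r: E for r in ("cytoplasm", "nucleoplasm", "cage", "lamina")},
            poisson={r: nu for r in ("cytoplasm", "nucleoplasm", "cage", "lamina")})
        rho0 = 0.01
        model = build_model(materials=mats,
                            active=ActiveState(rho0=rho0, sigma_mt=0.0,
                                               polarization="none", n_steps=2))
        # apply the isotropic contractility everywhere, not only in the
        # labelled cytoplasm, to realize the homogeneous closed-form state
        from cardionuc.mech import model as M
        E_els = model.mesh.n_elements
        rho = np.zeros((E_els, 4))
        rho[:, :3] = rho0
        U = model.newton(np.zeros(2 * model.mesh.n_nodes), rho)
        assert U is not None
        mu = E / (2 * (1 + nu))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        expected = -rho0 / (2 * (lam + mu))
        nodes = model.mesh.nodes
        lateral = np.flatnonzero(np.abs(nodes[:, 0] - model.geometry.cell_radius) < 1e-6)
        u_r = U.reshape(-1, 2)[lateral, 0]
        realized = u_r / model.geometry.cell_radius
        assert np.max(np.abs(realized - expected)) < 0.02 * abs(expected)

    def test_wt_field_qualitative(self, wt_solution):
        sol = wt_solution
        m = sol.model.mesh
        u = sol.U.reshape(-1, 2)
        # cell contracts radially at the lateral surface
        lateral = np.flatnonzero(np.abs(m.nodes[:, 0] - sol.model.geometry.cell_radius) < 1e-6)
        assert np.all(u[lateral, 0] < 0)
        # cell length exactly constant (fixed ends)
        assert sol.cell_axial_strain < 1e-8
        # axisymmetry: no radial motion on the axis
        assert np.max(np.abs(u[m.axis_nodes, 0])) < 1e-12
        # nucleus elongates along the cell axis
        assert sol.nuclear_aspect_ratio > 1.0

    def test_equilibrium_residual_converged(self, wt_solution):
        """The stored state satisfies equilibrium under its active field."""
        model = wt_solution.model
        R = model.residual(wt_solution.U, wt_solution.sigma_act)
        ref = np.linalg.norm(model.residual(
            np.zeros_like(wt_solution.U), wt_solution.sigma_act)[model.free])
        assert np.linalg.norm(R[model.free]) < 1e-6 * ref

    def test_deterministic_rerun_bit_identical(self):
        a = run_scenario("csDNKASH")
        b = run_scenario("csDNKASH")
        assert np.array_equal(a.U, b.U)
        assert a.summary() == b.summary()


class TestScenarios:
    def test_aspect_ratio_ordering(self, scenario_solutions):
        ar = {k: v.nuclear_aspect_ratio for k, v in scenario_solutions.items()}
        assert ar["WT"] < ar["csDNKASH"] < ar["LMNA_mut_csDNKASH"]

    def test_mutant_with_intact_cage_near_wt(self, scenario_solutions):
        ar_wt = scenario_solutions["WT"].nuclear_aspect_ratio
        ar_mut = scenario_solutions["LMNA_mut"].nuclear_aspect_ratio
        assert abs(ar_mut - ar_wt) / ar_wt < 0.15

    def test_unknown_scenario_rejected(self):
        from cardionuc.errors import ConfigError
        with pytest.raises(ConfigError):
            run_scenario("nonsense")

    def test_ar_monotone_in_cage_stress(self):
        """Nuclear AR non-increasing in sigma_MT at fixed lamina modulus."""
        ars = []
        for smt in (0.5, 1.5, 2.6, 3.8):
            model = build_model(active=ActiveState(sigma_mt=smt))
            ars.append(solve_ramp(model).nuclear_aspect_ratio)
        assert np.all(np.diff(ars) < 0)

    def test_nuclear_volume_change_directions(self, scenario_solutions):
        """Compressive prestress shrinks the nucleus in every scenario, and
        the elongated cage-disrupted nuclei lose the most volume (direction
        -only check; magnitudes are not anchored)."""
        dv = {k: v.nuclear_volume_change for k, v in scenario_solutions.items()}
        assert all(v < 0 for v in dv.values())
        assert dv["LMNA_mut_csDNKASH"] < dv["WT"]


class TestSweep:
    def test_two_point_grid_bookkeeping(self):
        out = sweep_enrichment(enrichment_grid=[1.0, 2.2])
        assert len(out) == 2
        assert not out["failed"].any()

    def test_plateau_and_low_enrichment_maximum(self):
        grid = np.linspace(0.4, 3.0, 7)
        out = sweep_enrichment(enrichment_grid=grid)
        ar = out["aspect_ratio"].to_numpy()
        assert np.argmax(ar) == 0                      # AR maximal as e -> 0
        plateau = ar[-3:].mean()
        assert abs(ar[-1] - plateau) / plateau < 0.05  # flat top of the curve
        assert np.all(np.diff(ar) < 0)                 # monotone decreasing

    def test_sweep_is_biphasic_under_piecewise_fit(self):
        from cardionuc.regression import piecewise_linear_fit
        grid = np.linspace(0.4, 3.0, 10)
        out = sweep_enrichment(enrichment_grid=grid)
        fit = piecewise_linear_fit(out[["enrichment", "aspect_ratio"]])
        assert fit.slope_below < 0
        assert abs(fit.slope_above) < 0.25 * abs(fit.slope_below)


class TestInstabilityMachinery:
    def test_needs_five_levels(self):
        with pytest.raises(ValueError):
            detect_tip_instability([1.0, 2.0], lamina_modulus=10.0)

    def test_high_stress_scan_flags_tip_shift(self):
        """At far-supraphysiological cage stress the max-principal-stress
        location does cross to the nuclear tip and a critical value is
        interpolated."""
        cfg = {"active": ActiveState(n_steps=40)}
        scan = detect_tip_instability(np.linspace(3.8, 7.6, 5),
                                      lamina_modulus=10.0, config=cfg)
        assert scan["instability"]
        assert scan["critical_sigma_mt"] is not None
        assert 3.8 <= scan["critical_sigma_mt"] <= 7.6

    def test_rescue_returns_stress_to_middle_and_elongates(self):
        """From a tip-localized state, reducing cage stress and stiffness
        (simulated LINC disruption) moves the maximum principal stress back
        to the nuclear middle while the nucleus elongates."""
        mats = MechMaterials()
        mats.moduli["lamina"] = 10.0
        tip_state = solve_ramp(build_model(
            materials=mats, active=ActiveState(sigma_mt=6.65, n_steps=40)))
        s_tip, _ = tip_state.lamina_max_principal_location()
        assert s_tip > 0.8
        # LINC disruption returns the cage to 0.3x its *physiological*
        # stress and stiffness (the csDNKASH scenario fractions)
        rescued = solve_ramp(build_model(
            materials=MechMaterials(moduli={**mats.moduli, "cage": 8.0 * 0.3},
                                    poisson=dict(mats.poisson)),
            active=ActiveState(sigma_mt=3.8 * 0.3, n_steps=40)))
        s_rescued, _ = rescued.lamina_max_principal_location()
        assert s_rescued < 0.5
        assert rescued.nuclear_aspect_ratio > tip_state.nuclear_aspect_ratio

    def test_mesh_convergence_of_ar_and_probes(self, wt_solution):
        coarse = wt_solution
        fine = solve_ramp(build_model(refine=1.5))
        assert fine.nuclear_aspect_ratio == pytest.approx(
            coarse.nuclear_aspect_ratio, rel=0.03)
        pc = probe_stresses(coarse)
        pf = probe_stresses(fine)
        for key in ("myofibril_tension_max", "mt_axial_compression_max"):
            assert pf[key] == pytest.approx(pc[key], rel=0.2)
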