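import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poroperf import fem
from poroperf import meshing as M
from poroperf import postproc as PP


@pytest.fixture(scope="module")
def linear_z_solution():
    """Single-compartment p = z on the unit cube (u = -grad p = -e_z)."""
    mesh = M.build_unit_cube_mesh(3)
    fields = fem.FieldSpec(K=[1.0], beta=np.zeros((1, 1)))
    bcs = fem.BCSpec(dirichlet=[(0, M.TOP, 1.0), (0, M.BOTTOM, 0.0)])
    return mesh, fem.solve(fem.assemble(mesh, fields, bcs, 1))


class TestDarcyVelocity:
    def test_constant_gradient_field(self, linear_z_solution):
        mesh, sol = linear_z_solution
        vel = PP.darcy_velocity(sol, 0, 1.0)
        assert np.abs(vel.cell_average() - [0, 0, -1]).max() < 1e-12

    def test_anisotropy_annihilates_lateral_gradient(self):
        """K = diag(0,0,k): a pressure varying only in x drives no flow."""
        mesh = M.build_unit_cube_mesh(2)
        space = fem.FESpace(mesh, 1)
        sol = fem.PressureSolution(mesh, 1, space,
                                   np.array([space.dof_coords[:, 0]]))
        vel = PP.darcy_velocity(sol, 0, np.diag([0.0, 0.0, 2.0]))
        assert np.abs(vel.cell_average()).max() < 1e-13

    def test_projection_is_idempotent(self, linear_z_solution):
        mesh, sol = linear_z_solution
        proj = PP.darcy_velocity(sol, 0, 1.0, target_order=1)
        assert np.abs(proj.nodal - [0, 0, -1]).max() < 1e-10
        reproj = PP.project_nodal_velocity(1, mesh, proj.nodal)
        cells = np.arange(mesh.n_cells)
        pts = np.array([[0.25, 0.25, 0.25]])
        assert np.allclose(proj.eval_in_cells(cells, pts),
                           reproj.eval_in_cells(cells, pts), atol=1e-12)

    def test_unsupported_projection_order(self, linear_z_solution):
        _, sol = linear_z_solution
        with pytest.raises(ValueError):
            PP.darcy_velocity(sol, 0, 1.0, target_order=3)


class TestSurfaceFlux:
    def test_uniform_downward_flow(self, linear_z_solution):
        mesh, sol = linear_z_solution
        q = PP.surface_flux(PP.darcy_velocity(sol, 0, 1.0), mesh)
        assert q[M.TOP] == pytest.approx(1.0, abs=1e-12)       # entering
        assert q[M.BOTTOM] == pytest.approx(-1.0, abs=1e-12)   # leaving
        for lab in (M.XMIN, M.XMAX, M.YMIN, M.YMAX):
            assert q[lab] == pytest.approx(0.0, abs=1e-12)

    def test_closed_constant_field_sums_to_zero(self, linear_z_solution):
        mesh, sol = linear_z_solution
        q = PP.surface_flux(PP.darcy_velocity(sol, 0, 1.0), mesh)
        assert q["total"] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_label_rejected(self, linear_z_solution):
        mesh, sol = linear_z_solution
        with pytest.raises(M.MeshError):
            PP.surface_flux(PP.darcy_velocity(sol, 0, 1.0), mesh, labels=[99])

    def test_manufactured_exact_inlet_flux(self, ms_case):
        """Facet quadrature of the exact arteriole velocity over z=1 equals
        the symbolic surface integral 2 (int f)^2 = 128/225."""
        mesh = M.build_unit_cube_mesh(8)
        space = fem.FESpace(mesh, 2)
        coeffs = np.array([ms_case.exact[i](space.dof_coords) for i in range(3)])
        sol = fem.PressureSolution(mesh, 2, space, coeffs)
        vel = PP.darcy_velocity(sol, 0, ms_case.K[0])
        q = PP.surface_flux(vel, mesh, labels=[M.TOP], degree=10)
        # oracle: -K1 grad p1 . n on z=1 is -2 f(x) f(y); int f = 8/15.
        # The P2 interpolant of the quartic solution carries a small
        # interpolation error, hence the loose-ish tolerance.
        assert q[M.TOP] == pytest.approx(128.0 / 225.0, rel=2e-3)


class TestVolumetricFlow:
    def test_constant_difference(self):
        mesh = M.build_unit_cube_mesh(2)
        space = fem.FESpace(mesh, 1)
        c = 3.5
        coeffs = np.vstack([np.full(space.n_dofs, c), np.zeros(space.n_dofs)])
        sol = fem.PressureSolution(mesh, 1, space, coeffs)
        beta = np.zeros((mesh.n_cells, 2, 2))
        beta[:, 0, 1] = beta[:, 1, 0] = 2.0
        Q, av = PP.volumetric_flow(sol, beta)
        assert Q == pytest.approx(2.0 * c, rel=1e-12)

    def test_region_averages_weight_by_volume(self):
        mesh = M.build_box_mesh((2, 2, 2), grey_above_z=0.5)
        space = fem.FESpace(mesh, 1)
        # p1 - p2 = 1 below the interface, 3 above it
        z = space.dof_coords[:, 2]
        p1 = np.where(z > 0.5, 3.0, 1.0)
        # make it piecewise-affine: interpolate z in [0.5, x] linearly
        p1 = 1.0 + 2.0 * np.clip((z - 0.25) / 0.5, 0.0, 1.0)
        sol = fem.PressureSolution(mesh, 1, space, np.vstack([p1, np.zeros_like(p1)]))
        beta = np.zeros((mesh.n_cells, 2, 2))
        beta[:, 0, 1] = beta[:, 1, 0] = 1.0
        Q, av = PP.volumetric_flow(sol, beta)
        assert av[M.GREY] > av[M.WHITE]
        vol = mesh.cell_volumes()
        F = PP.cell_perfusion(sol, beta)
        manual = {lab: 6000 * np.sum(F[mesh.cell_labels == lab]
                                     * vol[mesh.cell_labels == lab])
                  / vol[mesh.cell_labels == lab].sum()
                  for lab in (M.GREY, M.WHITE)}
        assert av[M.GREY] == pytest.approx(manual[M.GREY], rel=1e-12)
        assert av[M.WHITE] == pytest.approx(manual[M.WHITE], rel=1e-12)


class TestFluxReport:
    def test_relative_difference_formula(self):
        rep = PP.FluxReport(Q_gamma=95.0, Q_omega=100.0,
                            delta_r_percent=(95.0 - 100.0) / 100.0 * 100)
        assert rep.delta_r_percent == pytest.approx(-5.0)

    def test_inlet_flux_recovered(self):
        """Two uncoupled compartments, p1 = z: the report's surface flux
        integrates to the uniform unit inflow through TOP."""
        mesh = M.build_unit_cube_mesh(2)
        fields = fem.FieldSpec(K=[1.0, 1.0], beta=np.zeros((2, 2)))
        bcs = fem.BCSpec(dirichlet=[(0, M.TOP, 1.0), (0, M.BOTTOM, 0.0),
                                    (1, M.TOP, 0.0), (1, M.BOTTOM, 0.0)])
        sol = fem.solve(fem.assemble(mesh, fields, bcs, 1))
        beta = np.zeros((mesh.n_cells, 2, 2))
        rep = PP.flux_report(sol, beta, 1.0, inlet_labels=[M.TOP])
        assert rep.Q_gamma == pytest.approx(1.0, abs=1e-12)
        assert rep.Q_omega == pytest.approx(0.0, abs=1e-14)


class TestInfarct:
    def test_no_drop_no_infarct(self):
        F = np.ones(10)
        vol = np.ones(10)
        assert PP.infarct_fraction(F, F, vol) == 0.0

    def test_half_domain_deep_drop(self):
        F = np.ones(10)
        occ = F.copy()
        occ[:5] = 0.2
        assert PP.infarct_fraction(F, occ, np.ones(10)) == pytest.approx(0.5)

    def test_boundary_is_strict(self):
        F = np.ones(4)
        occ = np.full(4, 0.3)          # exactly 70% drop: not infarcted
        assert PP.infarct_fraction(F, occ, np.ones(4)) == 0.0

    def test_mismatched_fields_rejected(self):
        with pytest.raises(ValueError):
            PP.infarct_fraction(np.ones(3), np.ones(4), np.ones(3))

    @given(st.integers(min_value=1, max_value=200), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(0.5, 2.0, n)
        occ = F * rng.uniform(0.0, 1.2, n)
        vol = rng.uniform(0.1, 1.0, n)
        expected = sum(v for f, o, v in zip(F, occ, vol) if o < 0.3 * f)
        got = PP.infarct_fraction(F, occ, vol)
        assert got == pytest.approx(expected / vol.sum(), rel=1e-12)


class TestUniformInlet:
    def test_prescribed_flow_rate_recovered(self):
        """A Neumann inlet b = Q/area drives exactly Q through the patch."""
        mesh = M.build_unit_cube_mesh(2)
        Q = 0.75
        b = PP.uniform_inlet_value(mesh, M.TOP, Q)
        assert b == pytest.approx(Q, rel=1e-12)      # unit face area
        fields = fem.FieldSpec(K=[1.0], beta=np.zeros((1, 1)))
        bcs = fem.BCSpec(dirichlet=[(0, M.BOTTOM, 0.0)],
                         neumann=[(0, M.TOP, b)])
        sol = fem.solve(fem.assemble(mesh, fields, bcs, 1))
        q = PP.surface_flux(PP.darcy_velocity(sol, 0, 1.0), mesh,
                            labels=[M.TOP])
        assert q[M.TOP] == pytest.approx(Q, rel=1e-10)


class TestOcclusionBCs:
    def _bcs(self):
        return fem.BCSpec(dirichlet=[(0, M.TOP, 100.0), (0, M.TOP_OCCLUDED, 100.0),
                                     (2, M.TOP, 0.0), (2, M.TOP_OCCLUDED, 0.0)])

    def test_venule_condition_retained(self):
        occ = PP.make_occlusion_bcs(self._bcs(), M.TOP_OCCLUDED)
        assert (2, M.TOP_OCCLUDED, 0.0) in occ.dirichlet
        assert not any(c == 0 and lab == M.TOP_OCCLUDED
                       for c, lab, _ in occ.dirichlet)
        assert (0, M.TOP_OCCLUDED, 0.0) in occ.neumann

    def test_label_without_arteriole_dbc_rejected(self):
        with pytest.raises(M.MeshError):
            PP.make_occlusion_bcs(self._bcs(), M.BOTTOM)

    def test_occluding_every_inlet_rejected(self):
        bcs = PP.make_occlusion_bcs(self._bcs(), M.TOP_OCCLUDED)
        with pytest.raises(fem.WellPosednessError):
            PP.make_occlusion_bcs(bcs, M.TOP)

    def test_occlusion_reduces_total_perfusion(self, internal_params):
        """Directly simulated healthy/occluded pair on the layered box."""
        from poroperf.calibration import CubeScenario
        out = CubeScenario(n=(2, 2, 5)).outputs(
            __import__("poroperf").ParameterSet())
        assert out["F_occluded"] < out["F_healthy"]
        assert 0.0 <= out["infarct_fraction"] <= 1.0
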