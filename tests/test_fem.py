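import numpy as np
import pytest

from poroperf import fem
from poroperf import meshing as M


def single_compartment_fields(S=None):
    return fem.FieldSpec(K=[1.0], beta=np.zeros((1, 1)), S=S)


class TestExactness:
    def test_p1_reproduces_affine_field(self):
        """Patch test: P1 is exact for p = x with matching boundary data."""
        mesh = M.build_unit_cube_mesh(2)
        bcs = fem.BCSpec(dirichlet=[(0, M.XMIN, lambda p: p[:, 0]),
                                    (0, M.XMAX, lambda p: p[:, 0])])
        sol = fem.solve(fem.assemble(mesh, single_compartment_fields(), bcs, 1))
        assert np.abs(sol.coeffs[0] - sol.space.dof_coords[:, 0]).max() < 1e-12

    def test_p2_reproduces_quadratic_field(self):
        """P2 is exact for p = x^2 (source -2 balances the Laplacian)."""
        mesh = M.build_unit_cube_mesh(2)
        fields = single_compartment_fields(S=[lambda p: np.full(len(p), -2.0)])
        bcs = fem.BCSpec(dirichlet=[(0, M.XMIN, lambda p: p[:, 0] ** 2),
                                    (0, M.XMAX, lambda p: p[:, 0] ** 2)])
        sol = fem.solve(fem.assemble(mesh, fields, bcs, 2))
        assert np.abs(sol.coeffs[0] - sol.space.dof_coords[:, 0] ** 2).max() < 1e-10


class TestDofBookkeeping:
    @pytest.mark.parametrize("n_edge, order, n_dof",
                             [(2, 1, 81), (4, 1, 375), (8, 1, 2187),
                              (2, 2, 375), (4, 2, 2187), (8, 2, 14739)])
    def test_coupled_system_dof_counts(self, ms_case, n_edge, order, n_dof):
        mesh = M.build_unit_cube_mesh(n_edge)
        system = fem.assemble(mesh, ms_case.field_spec(mesh), ms_case.bcs(),
                              order)
        assert system.n_dofs == n_dof

    @pytest.mark.parametrize("n_edge", range(1, 17))
    def test_p1_scalar_dofs_match_lattice(self, n_edge):
        mesh = M.build_unit_cube_mesh(n_edge)
        assert fem.FESpace(mesh, 1).n_dofs == (n_edge + 1) ** 3

    @pytest.mark.parametrize("n_edge", [1, 2, 3, 5])
    def test_p2_scalar_dofs_match_refined_lattice(self, n_edge):
        mesh = M.build_unit_cube_mesh(n_edge)
        assert fem.FESpace(mesh, 2).n_dofs == (2 * n_edge + 1) ** 3


class TestAssembledOperator:
    def test_symmetric_and_positive_definite(self, ms_case):
        mesh = M.build_unit_cube_mesh(2)
        system = fem.assemble(mesh, ms_case.field_spec(mesh), ms_case.bcs(), 1)
        A = system.A
        assert abs(A - A.T).max() < 1e-12
        free = np.ones(A.shape[0], bool)
        free[system.dirichlet_idx] = False
        eigs = np.linalg.eigvalsh(A[free][:, free].toarray())
        assert eigs.min() > 0

    def test_pure_neumann_rejected(self):
        mesh = M.build_unit_cube_mesh(2)
        bcs = fem.BCSpec(neumann=[(0, M.TOP, 1.0)])
        with pytest.raises(fem.WellPosednessError, match="Neumann"):
            fem.assemble(mesh, single_compartment_fields(), bcs, 1)

    def test_conflicting_bc_rejected(self):
        mesh = M.build_unit_cube_mesh(2)
        bcs = fem.BCSpec(dirichlet=[(0, M.TOP, 1.0)],
                         neumann=[(0, M.TOP, 0.5)])
        with pytest.raises(fem.WellPosednessError, match="both"):
            fem.assemble(mesh, single_compartment_fields(), bcs, 1)

    def test_indefinite_permeability_rejected(self):
        mesh = M.build_unit_cube_mesh(1)
        fields = fem.FieldSpec(K=[np.diag([1.0, 1.0, -1.0])],
                               beta=np.zeros((1, 1)))
        bcs = fem.BCSpec(dirichlet=[(0, M.TOP, 0.0)])
        with pytest.raises(ValueError, match="indefinite"):
            fem.assemble(mesh, fields, bcs, 1)


class TestSolvers:
    def test_direct_and_iterative_agree(self, ms_case, cube4):
        system = fem.assemble(cube4, ms_case.field_spec(cube4), ms_case.bcs(), 1)
        direct = fem.solve(system, method="direct")
        iterative = fem.solve(system, method="iterative", rtol=1e-12)
        diff = np.abs(direct.coeffs - iterative.coeffs).max()
        assert diff < 1e-8 * max(1.0, np.abs(direct.coeffs).max())

    def test_dirichlet_values_held_exactly(self, ms_case, cube4):
        system = fem.assemble(cube4, ms_case.field_spec(cube4), ms_case.bcs(), 2)
        sol = fem.solve(system)
        top = sol.space.facet_dofs(cube4.facets_with_label(M.TOP))
        exact = ms_case.exact[0](sol.space.dof_coords[top])
        assert np.abs(sol.coeffs[0][top] - exact).max() < 1e-12

    def test_periodic_pairs_match_exactly(self, ms_case, cube4):
        system = fem.assemble(cube4, ms_case.field_spec(cube4), ms_case.bcs(), 1)
        sol = fem.solve(system)
        coords = sol.space.dof_coords
        on_x0 = np.abs(coords[:, 0]) < 1e-12
        for comp in range(3):
            vals = sol.coeffs[comp]
            for i in np.flatnonzero(on_x0):
                j = np.flatnonzero(np.all(np.abs(
                    coords - (coords[i] + [1, 0, 0])) < 1e-10, axis=1))
                assert vals[j[0]] == vals[i]  # identified, hence bitwise equal


class TestProbing:
    def test_point_outside_domain_rejected(self, ms_case, cube4):
        system = fem.assemble(cube4, ms_case.field_spec(cube4), ms_case.bcs(), 1)
        sol = fem.solve(system)
        with pytest.raises(ValueError, match="outside"):
            fem.probe(sol, (1.5, 0.5, 0.5), 0)

    def test_gradient_probe_on_interpolated_exact_field(self, ms_case):
        """dp1/dz at (0.5, 0.5, 1) of the exact field is 2 (symbolic oracle);
        the P2 interpolant of p1 reproduces it closely."""
        mesh = M.build_unit_cube_mesh(4)
        space = fem.FESpace(mesh, 2)
        coeffs = np.array([ms_case.exact[i](space.dof_coords) for i in range(3)])
        sol = fem.PressureSolution(mesh, 2, space, coeffs)
        g_exact = ms_case.exact_gradient(0, (0.5, 0.5, 1.0))
        assert g_exact[2] == pytest.approx(2.0, abs=1e-12)
        g = fem.probe(sol, (0.5, 0.5, 1.0), 0, "gradient")
        assert g[2] == pytest.approx(2.0, rel=0.05)

    def test_value_probe_matches_interpolant(self, ms_case, cube4):
        space = fem.FESpace(cube4, 1)
        coeffs = np.array([space.dof_coords[:, 2]])
        sol = fem.PressureSolution(cube4, 1, space, coeffs)
        assert fem.probe(sol, (0.3, 0.7, 0.25), 0) == pytest.approx(0.25, abs=1e-12)


class TestL2Error:
    def test_zero_for_exactly_representable_field(self, cube4):
        space = fem.FESpace(cube4, 1)
        coeffs = np.array([space.dof_coords @ [1.0, 2.0, 3.0]])
        sol = fem.PressureSolution(cube4, 1, space, coeffs)
        err = fem.l2_error(sol, [lambda p: p @ np.array([1.0, 2.0, 3.0])])
        assert err < 1e-13

    def test_aggregates_compartments_in_quadrature(self, cube4):
        """Root-sum-square aggregation over compartments."""
        space = fem.FESpace(cube4, 1)
        coeffs = np.zeros((2, space.n_dofs))
        sol = fem.PressureSolution(cube4, 1, space, coeffs)
        one = lambda p: np.ones(len(p))
        err = fem.l2_error(sol, [one, one])
        assert err == pytest.approx(np.sqrt(2.0), rel=1e-12)
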