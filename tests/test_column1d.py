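import numpy as np
import pytest

from poroperf import column1d as C
from poroperf import params as P
from poroperf.params import alpha_star


class TestCompanion:
    def test_single_compartment_nilpotent(self):
        A, B = C.build_companion(np.array([[0.0]]))
        assert np.array_equal(B, [[0.0]])
        assert np.array_equal(A, [[0.0, 1.0], [0.0, 0.0]])

    def test_two_compartment_eigenvalues(self):
        b = 3.0
        _, B = C.build_companion(np.array([[0.0, b], [b, 0.0]]))
        eig = np.sort(np.linalg.eigvals(B).real)
        assert eig == pytest.approx([0.0, 2 * b], abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_row_sum_vector_annihilated(self, n, rng):
        alpha = rng.random((n, n))
        np.fill_diagonal(alpha, 0.0)
        _, B = C.build_companion(alpha)
        assert np.abs(B @ np.ones(n)).max() < 1e-12

    def test_rejects_non_square(self):
        with pytest.raises(C.ColumnError):
            C.build_companion(np.zeros((2, 3)))


def two_compartment_problem(k, beta, L, cpp):
    """Symmetric antisymmetric-DBC pair with sealed far end."""
    bcs = [C.ColumnBC(0, 0, "dirichlet", cpp),
           C.ColumnBC(1, 0, "dirichlet", -cpp),
           C.ColumnBC(0, 1, "neumann", 0.0),
           C.ColumnBC(1, 1, "neumann", 0.0)]
    bmat = np.array([[0.0, beta], [beta, 0.0]])
    return C.ColumnProblem(k=np.array([k, k]), subdomains=[(L, bmat)], bcs=bcs)


class TestAnalyticOracles:
    def test_uncoupled_single_compartment_is_linear(self):
        """beta = 0 reduces to the Laplace equation: p = 1 - x/l."""
        prob = C.ColumnProblem(k=np.array([2.0]),
                               subdomains=[(4.0, np.zeros((1, 1)))],
                               bcs=[C.ColumnBC(0, 0, "dirichlet", 1.0),
                                    C.ColumnBC(0, 1, "dirichlet", 0.0)])
        sol = C.solve_column(prob)
        x = np.linspace(0, 4, 9)
        assert np.abs(sol.pressure(x)[0] - (1 - x / 4)).max() < 1e-12

    def test_two_compartment_cosh_closed_form(self):
        """Antisymmetric two-compartment exchange: the pressure difference
        follows d = 2 cpp cosh(sqrt(2 alpha)(l-x)) / cosh(sqrt(2 alpha) l)
        (independent closed-form oracle)."""
        k, beta, L, cpp = 2.0, 0.5, 3.0, 10.0
        sol = C.solve_column(two_compartment_problem(k, beta, L, cpp))
        a = np.sqrt(2 * beta / k)
        x = np.linspace(0, L, 41)
        d_exact = 2 * cpp * np.cosh(a * (L - x)) / np.cosh(a * L)
        p = sol.pressure(x)
        assert np.abs((p[0] - p[1]) - d_exact).max() < 1e-8 * cpp

    def test_headline_perfusion_averages(self, reference_params):
        """Reference parameters, 13.55 + 7.99 mm column: whole/grey/white
        perfusion round to 43/56/21 ml/min/100ml."""
        sol = C.solve_column(C.default_column_problem(reference_params))
        av = C.column_averages(sol)
        assert round(av.F_total) == 43
        assert round(av.F_sub[0]) == 56
        assert round(av.F_sub[1]) == 21

    def test_interface_continuity(self, reference_params):
        sol = C.solve_column(C.default_column_problem(reference_params))
        eps = 1e-9
        for f in (sol.pressure, sol.pressure_gradient):
            left = f(np.array([13.55 - eps]))
            right = f(np.array([13.55 + eps]))
            assert np.abs(left - right).max() < 1e-6 * np.abs(left).max()

    def test_boundary_conditions_satisfied(self, reference_params, internal_params):
        sol = C.solve_column(C.default_column_problem(reference_params))
        p0 = sol.pressure(np.array([0.0]))
        qL = sol.pressure_gradient(np.array([21.54]))
        assert p0[0, 0] == pytest.approx(internal_params.cpp_pa, rel=1e-10)
        assert p0[2, 0] == pytest.approx(0.0, abs=1e-8 * internal_params.cpp_pa)
        assert np.abs(qL).max() < 1e-8 * internal_params.cpp_pa / 21.54
        q0 = sol.pressure_gradient(np.array([0.0]))
        assert abs(q0[1, 0]) < 1e-8 * internal_params.cpp_pa / 21.54

    def test_mode_count_is_2n_per_subdomain(self, reference_params):
        sol = C.solve_column(C.default_column_problem(reference_params))
        for md in sol.modes:
            assert md.n_modes == 2 * 3

    def test_zero_cpp_gives_zero_everywhere(self, reference_params):
        from dataclasses import replace
        internal = P.to_internal(reference_params)
        internal.cpp_pa = 0.0
        sol = C.solve_column(C.default_column_problem(internal))
        av = C.column_averages(sol)
        assert abs(av.F_total) < 1e-12
        assert np.abs(av.pressure).max() < 1e-12


class TestConservationAndSimilarity:
    def test_flux_balance(self, reference_params, internal_params):
        """Steady-state mass conservation: arteriole inflow at the pial end
        equals the integrated arteriole-capillary exchange and the venous
        outflow."""
        prob = C.default_column_problem(reference_params)
        sol = C.solve_column(prob)
        q0 = sol.pressure_gradient(np.array([0.0]))[:, 0]
        inflow = -internal_params.k[0] * q0[0]
        outflow = internal_params.k[2] * q0[2]
        # closed-form integral of F over the column from the exact averages
        av = C.column_averages(sol)
        exchange = av.F_total / 6000.0 * prob.length
        assert inflow == pytest.approx(exchange, rel=1e-8)
        assert inflow == pytest.approx(abs(outflow), rel=1e-8)
        assert q0[2] > 0  # venule pressure rises away from its outlet

    def test_dimensionless_similarity(self, internal_params):
        """Solving the alpha*-scaled dimensionless problem and rescaling
        reproduces the dimensional profiles."""
        l_s = internal_params.cpp_pa, 21.54
        p_s, l_ref = internal_params.cpp_pa, 21.54
        prob_dim = C.default_column_problem(internal_params)
        sol_dim = C.solve_column(prob_dim)

        subs = []
        for length, beta in prob_dim.subdomains:
            a = alpha_star(l_ref, beta, internal_params.k)
            subs.append((length / l_ref, a))
        bcs = [C.ColumnBC(0, 0, "dirichlet", 1.0),
               C.ColumnBC(2, 0, "dirichlet", 0.0),
               C.ColumnBC(1, 0, "neumann", 0.0),
               C.ColumnBC(0, 1, "neumann", 0.0),
               C.ColumnBC(1, 1, "neumann", 0.0),
               C.ColumnBC(2, 1, "neumann", 0.0)]
        prob_star = C.ColumnProblem(k=np.ones(3), subdomains=subs, bcs=bcs)
        sol_star = C.solve_column(prob_star)
        x = np.linspace(0, 21.54, 101)
        dim = sol_dim.pressure(x)
        scaled = p_s * sol_star.pressure(x / l_ref)
        assert np.abs(dim - scaled).max() < 1e-10 * p_s

    def test_doubling_cpp_doubles_everything(self, reference_params):
        from dataclasses import replace
        sol1 = C.solve_column(C.default_column_problem(reference_params))
        sol2 = C.solve_column(C.default_column_problem(
            replace(reference_params, cpp=2 * reference_params.cpp)))
        av1, av2 = C.column_averages(sol1), C.column_averages(sol2)
        assert av2.F_total == pytest.approx(2 * av1.F_total, rel=1e-12)
        assert np.allclose(av2.pressure, 2 * av1.pressure, rtol=1e-12)


class TestFiniteElementCrossCheck:
    def test_uncoupled_linear_case_exact_at_p1(self):
        prob = C.ColumnProblem(k=np.array([1.0]),
                               subdomains=[(2.0, np.zeros((1, 1)))],
                               bcs=[C.ColumnBC(0, 0, "dirichlet", 5.0),
                                    C.ColumnBC(0, 1, "dirichlet", 1.0)])
        x, p = C.solve_column_fe(prob, n_cells=10, order=1)
        assert np.abs(p[0] - (5.0 - 2.0 * x)).max() < 1e-10

    def test_fe_matches_analytic_profiles(self, reference_params, internal_params):
        """100 P1 elements against the modal solution: below 1% of CPP."""
        prob = C.default_column_problem(reference_params)
        x, p = C.solve_column_fe(prob, n_cells=100, order=1)
        exact = C.solve_column(prob).pressure(x)
        assert np.abs(p - exact).max() < 0.01 * internal_params.cpp_pa

    def test_fe_averages_converge_to_analytic(self, reference_params):
        prob = C.default_column_problem(reference_params)
        exact = C.column_averages(C.solve_column(prob))
        fe = C.fe_averages(prob, n_cells=1000)
        assert fe.F_total == pytest.approx(exact.F_total, rel=1e-3)
        assert np.allclose(fe.F_sub, exact.F_sub, rtol=1e-3)

    def test_fe_converges_at_second_order(self, reference_params):
        prob = C.default_column_problem(reference_params)
        exact = C.solve_column(prob)
        errs = []
        for n in (50, 100, 200, 400):
            x, p = C.solve_column_fe(prob, n_cells=n, order=1)
            errs.append(np.abs(p - exact.pressure(x)).max())
        rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(rates > 1.7)


class TestAveragesIdentity:
    def test_total_is_length_weighted_mean(self, reference_params):
        av = C.column_averages(C.solve_column(
            C.default_column_problem(reference_params)))
        mixed = (av.F_sub[0] * 13.55 + av.F_sub[1] * 7.99) / 21.54
        assert av.F_total == pytest.approx(mixed, rel=1e-12)
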