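"""Analytical and finite-element solution of the 1D tissue column.

A column of brain tissue stretches from the pial surface (x = 0) to the
ventricular surface (x = l = l_G + l_W), with a grey-matter layer next to
the cortex and a white-matter layer beneath it.  In each layer the coupled
system reduces to constant-coefficient ODEs

    k_i p_i'' = sum_j beta_ij (p_i - p_j),

with identical permeabilities but layer-specific coupling matrices.
Writing r = [p; q] with q = p' gives r' = A r, A = [[0, I], [B, 0]],
B = diag(alpha e) - alpha, alpha_ij = beta_ij / k_i.  B annihilates the
constant vector e by construction, so A carries a defective zero
eigenvalue: the pure exponential eigen-expansion is completed with
constant and linear-in-x polynomial modes (two per connected coupling
block).  Exponential modes are anchored at the nearer subdomain end,
exp(-sqrt(mu) * distance), so the boundary-condition system stays well
scaled even when coupling is stiff.

Default boundary conditions mirror the 3D brain model: arteriole pressure
CPP and venule pressure 0 at the pial end, zero capillary flux there, and
zero flux for every compartment at the ventricular end.  Pressures are
relative to the venous outlet.

Perfusion is F = beta12 (p1 - p2); averages are exact integrals of the
modal expansion (closed-form antiderivatives, no quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg

from .params import InternalParams, ParameterSet, perfusion_to_clinical, to_internal

__all__ = [
    "ColumnProblem", "ColumnSolution", "ColumnAverages", "build_companion",
    "solve_column", "solve_column_fe", "column_averages", "default_column_problem",
]

_ZERO_EIG_TOL = 1e-9


class ColumnError(ValueError):
    """Raised for ill-posed column problems."""


def build_companion(alpha: np.ndarray):
    """Companion matrices of the first-order system r' = A r.

    B = diag(alpha e) - alpha (so B e = 0 for any admissible alpha) and
    A = [[0, I], [B, 0]].
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2 or alpha.shape[0] != alpha.shape[1]:
        raise ColumnError("alpha must be a square matrix")
    n = len(alpha)
    B = np.diag(alpha @ np.ones(n)) - alpha
    A = np.block([[np.zeros((n, n)), np.eye(n)], [B, np.zeros((n, n))]])
    return A, B


@dataclass
class ColumnBC:
    """One boundary condition: kind 'dirichlet' (p_i = value) or
    'neumann' (dp_i/dx = value) for compartment ``comp`` at ``end`` 0/1."""

    comp: int
    end: int          # 0 = pial (x=0), 1 = ventricular (x=l)
    kind: str         # 'dirichlet' | 'neumann'
    value: float


@dataclass
class ColumnProblem:
    """Two-layer (or general multi-layer) column problem specification."""

    k: np.ndarray                       # (n,) permeabilities, shared by layers
    subdomains: Sequence[tuple]         # [(length, beta matrix), ...] pial-first
    bcs: Sequence[ColumnBC]

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        if np.any(self.k <= 0):
            raise ColumnError("permeabilities must be positive")
        for length, _ in self.subdomains:
            if length <= 0:
                raise ColumnError("subdomain lengths must be positive")
        n = len(self.k)
        if len(self.bcs) != 2 * n:
            raise ColumnError(f"need exactly {2*n} boundary conditions, "
                              f"got {len(self.bcs)}")

    @property
    def n(self) -> int:
        return len(self.k)

    @property
    def breakpoints(self) -> np.ndarray:
        lengths = [l for l, _ in self.subdomains]
        return np.concatenate([[0.0], np.cumsum(lengths)])

    @property
    def length(self) -> float:
        return float(self.breakpoints[-1])


def default_column_problem(params: ParameterSet | InternalParams,
                           l_G: float = 13.55, l_W: float = 7.99) -> ColumnProblem:
    """Grey+white column with the brain model's boundary conditions."""
    internal = params if isinstance(params, InternalParams) else to_internal(params)
    bcs = [
        ColumnBC(0, 0, "dirichlet", internal.cpp_pa),
        ColumnBC(2, 0, "dirichlet", 0.0),
        ColumnBC(1, 0, "neumann", 0.0),
        ColumnBC(0, 1, "neumann", 0.0),
        ColumnBC(1, 1, "neumann", 0.0),
        ColumnBC(2, 1, "neumann", 0.0),
    ]
    return ColumnProblem(
        k=internal.k,
        subdomains=[(l_G, internal.beta_grey), (l_W, internal.beta_white)],
        bcs=bcs,
    )


@dataclass
class _SubdomainModes:
    """Modal basis of one layer: evaluators for p(x) and q(x) = p'(x).

    Modes: for each positive eigenvalue mu of B with eigenvector w, two
    anchored exponentials w*exp(-sqrt(mu)(x-xl)) and w*exp(-sqrt(mu)(xr-x));
    for each null vector w of B, a constant mode w and a linear mode w*x.
    """

    xl: float
    xr: float
    beta: np.ndarray
    mu: np.ndarray          # (m,) positive eigenvalues, one entry per exp pair
    W: np.ndarray           # (n, m) eigenvectors of positive eigenvalues
    W0: np.ndarray          # (n, m0) nullspace vectors

    @property
    def n_modes(self) -> int:
        return 2 * self.W.shape[1] + 2 * self.W0.shape[1]

    def eval(self, x) -> tuple[np.ndarray, np.ndarray]:
        """(p, q) arrays of shape (n, n_modes, len(x))."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        n = self.W.shape[0]
        P = np.zeros((n, self.n_modes, len(x)))
        Q = np.zeros_like(P)
        col = 0
        for m in range(self.W.shape[1]):
            s = np.sqrt(self.mu[m])
            w = self.W[:, m]
            eL = np.exp(-s * (x - self.xl))       # decays rightward
            eR = np.exp(-s * (self.xr - x))       # decays leftward
            P[:, col] = w[:, None] * eL
            Q[:, col] = -s * w[:, None] * eL
            P[:, col + 1] = w[:, None] * eR
            Q[:, col + 1] = s * w[:, None] * eR
            col += 2
        for m0 in range(self.W0.shape[1]):
            w = self.W0[:, m0]
            P[:, col] = w[:, None]
            # Q stays zero for the constant mode
            P[:, col + 1] = w[:, None] * x[None, :]
            Q[:, col + 1] = w[:, None]
            col += 2
        return P, Q

    def integral(self) -> np.ndarray:
        """Exact integrals of each mode's p over [xl, xr], shape (n, n_modes)."""
        n = self.W.shape[0]
        out = np.zeros((n, self.n_modes))
        L = self.xr - self.xl
        col = 0
        for m in range(self.W.shape[1]):
            s = np.sqrt(self.mu[m])
            w = self.W[:, m]
            val = (1.0 - np.exp(-s * L)) / s
            out[:, col] = w * val
            out[:, col + 1] = w * val
            col += 2
        for m0 in range(self.W0.shape[1]):
            w = self.W0[:, m0]
            out[:, col] = w * L
            out[:, col + 1] = w * 0.5 * (self.xr**2 - self.xl**2)
            col += 2
        return out


def _subdomain_modes(xl, xr, k, beta) -> _SubdomainModes:
    beta = np.asarray(beta, dtype=float)
    alpha = beta / np.asarray(k, dtype=float)[:, None]
    _, B = build_companion(alpha)
    mu, V = scipy.linalg.eig(B)
    if np.abs(mu.imag).max(initial=0.0) > 1e-10 * max(1.0, np.abs(mu).max()):
        # B is similar to a symmetric PSD matrix for symmetric beta and
        # positive k; complex pairs only arise for non-physical input.
        raise ColumnError("coupling matrix produced complex eigenvalues")
    mu, V = mu.real, V.real
    scale = max(1.0, mu.max(initial=1.0))
    null = mu < _ZERO_EIG_TOL * scale
    return _SubdomainModes(xl=float(xl), xr=float(xr), beta=beta,
                           mu=mu[~null], W=V[:, ~null], W0=V[:, null])


@dataclass
class ColumnSolution:
    """Modal solution of a multi-layer column problem."""

    problem: ColumnProblem
    modes: list = field(repr=False, default_factory=list)
    coefficients: list = field(repr=False, default_factory=list)
    condition_number: float = np.nan

    def subdomain_of(self, x: float) -> int:
        bp = self.problem.breakpoints
        idx = int(np.searchsorted(bp[1:-1], x, side="right"))
        return idx

    def _eval(self, x, deriv=False) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros((self.problem.n, len(x)))
        bp = self.problem.breakpoints
        for s, (md, C) in enumerate(zip(self.modes, self.coefficients)):
            if s == 0:
                mask = (x >= bp[s] - 1e-12) & (x <= bp[s + 1] + 1e-12)
            else:
                mask = (x > bp[s]) & (x <= bp[s + 1] + 1e-12)
            if not np.any(mask):
                continue
            P, Q = md.eval(x[mask])
            basis = Q if deriv else P
            out[:, mask] = np.einsum("nmx,m->nx", basis, C)
        return out

    def pressure(self, x) -> np.ndarray:
        """p_i(x) in Pa; shape (n, len(x))."""
        return self._eval(x, deriv=False)

    def pressure_gradient(self, x) -> np.ndarray:
        """q_i(x) = dp_i/dx in Pa/mm."""
        return self._eval(x, deriv=True)

    def perfusion(self, x) -> np.ndarray:
        """F(x) = beta12(x) (p1 - p2), volumetric exchange rate in 1/s."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        p = self.pressure(x)
        b12 = np.array([self.problem.subdomains[self.subdomain_of(xi)][1][0, 1]
                        for xi in x])
        return b12 * (p[0] - p[1])


def solve_column(problem: ColumnProblem,
                 cond_warn: float = 1e12) -> ColumnSolution:
    """Solve the layered column by eigen-modal expansion.

    Boundary rows come from the Dirichlet/Neumann conditions; interface
    rows enforce continuity of p_i and of dp_i/dx between adjacent layers
    (permeabilities are identical across layers, so derivative continuity
    coincides with flux continuity).
    """
    n = problem.n
    bp = problem.breakpoints
    modes = [_subdomain_modes(bp[s], bp[s + 1], problem.k, beta)
             for s, (_, beta) in enumerate(problem.subdomains)]
    sizes = [md.n_modes for md in modes]
    for s, sz in enumerate(sizes):
        if sz != 2 * n:
            raise ColumnError(f"subdomain {s}: found {sz} modes, expected {2*n}")
    offs = np.concatenate([[0], np.cumsum(sizes)])
    N = offs[-1]
    M = np.zeros((N, N))
    rhs = np.zeros(N)
    row = 0

    for bc in problem.bcs:
        s = 0 if bc.end == 0 else len(modes) - 1
        xb = bp[0] if bc.end == 0 else bp[-1]
        P, Q = modes[s].eval(xb)
        basis = P if bc.kind == "dirichlet" else Q
        M[row, offs[s]:offs[s + 1]] = basis[bc.comp, :, 0]
        rhs[row] = bc.value
        row += 1

    for s in range(len(modes) - 1):
        xi = bp[s + 1]
        Pl, Ql = modes[s].eval(xi)
        Pr, Qr = modes[s + 1].eval(xi)
        for i in range(n):
            M[row, offs[s]:offs[s + 1]] = Pl[i, :, 0]
            M[row, offs[s + 1]:offs[s + 2]] = -Pr[i, :, 0]
            row += 1
            M[row, offs[s]:offs[s + 1]] = Ql[i, :, 0]
            M[row, offs[s + 1]:offs[s + 2]] = -Qr[i, :, 0]
            row += 1

    if row != N:
        raise ColumnError(f"boundary/interface rows ({row}) do not close the "
                          f"{N}-coefficient system")
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e15:
        raise ColumnError("boundary-condition system is singular; check that "
                          "each compartment is constrained")
    if cond > cond_warn:
        import warnings
        warnings.warn(f"column BC system is ill-conditioned (cond={cond:.2e})",
                      RuntimeWarning, stacklevel=2)
    C = np.linalg.solve(M, rhs)
    coeffs = [C[offs[s]:offs[s + 1]] for s in range(len(modes))]
    return ColumnSolution(problem, modes, coeffs, cond)


# -- averages ------------------------------------------------------------------

@dataclass
class ColumnAverages:
    """Length-weighted averages; perfusion in clinical units."""

    pressure: np.ndarray               # (n,) whole-column <p_i> in Pa
    pressure_sub: np.ndarray           # (n_sub, n) per-layer <p_i>
    F_total: float                     # ml/min/100 ml
    F_sub: np.ndarray                  # (n_sub,) ml/min/100 ml


def column_averages(solution: ColumnSolution) -> ColumnAverages:
    """Exact (closed-form) layer and whole-column averages of p_i and F."""
    prob = solution.problem
    bp = prob.breakpoints
    n = prob.n
    p_sub = np.zeros((len(prob.subdomains), n))
    F_sub = np.zeros(len(prob.subdomains))
    lengths = np.diff(bp)
    for s, (md, C) in enumerate(zip(solution.modes, solution.coefficients)):
        ints = md.integral() @ C                   # (n,) integral of p_i
        p_sub[s] = ints / lengths[s]
        b12 = prob.subdomains[s][1][0, 1]
        F_sub[s] = b12 * (p_sub[s, 0] - p_sub[s, 1])
    w = lengths / lengths.sum()
    return ColumnAverages(
        pressure=w @ p_sub,
        pressure_sub=p_sub,
        F_total=float(perfusion_to_clinical(w @ F_sub)),
        F_sub=perfusion_to_clinical(F_sub),
    )


# -- independent 1D finite-element solve --------------------------------------

def solve_column_fe(problem: ColumnProblem, n_cells: int = 100,
                    order: int = 1):
    """Galerkin P1/P2 solve of the column system on a layered interval mesh.

    Returns (x_nodes, p) with p of shape (n, n_nodes).  Serves as the
    independent numerical cross-check of the modal solution and as the
    robust engine for parameter scans.
    """
    if n_cells < 2:
        raise ColumnError("need at least two cells")
    if order not in (1, 2):
        raise ColumnError("order must be 1 or 2")
    n = problem.n
    bp = problem.breakpoints
    lengths = np.diff(bp)
    # cells per layer proportional to length, >= 1
    counts = np.maximum(1, np.round(n_cells * lengths / lengths.sum()).astype(int))
    xs = [np.linspace(bp[s], bp[s + 1], counts[s] + 1) for s in range(len(lengths))]
    verts = np.concatenate([xs[0]] + [x[1:] for x in xs[1:]])
    cell_sub = np.concatenate([np.full(c, s) for s, c in enumerate(counts)])
    nc = len(verts) - 1

    if order == 1:
        nodes = verts
        cell_dofs = np.column_stack([np.arange(nc), np.arange(1, nc + 1)])
    else:
        mids = 0.5 * (verts[:-1] + verts[1:])
        nodes = np.concatenate([verts, mids])
        cell_dofs = np.column_stack([np.arange(nc), np.arange(1, nc + 1),
                                     len(verts) + np.arange(nc)])
    nd = len(nodes)
    h = np.diff(verts)

    if order == 1:
        Ke = np.array([[1.0, -1.0], [-1.0, 1.0]])
        Me = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
        Kes = Ke[None] / h[:, None, None]
        Mes = Me[None] * h[:, None, None]
    else:
        Ke = np.array([[7.0, 1.0, -8.0], [1.0, 7.0, -8.0], [-8.0, -8.0, 16.0]]) / 3.0
        Me = np.array([[4.0, -1.0, 2.0], [-1.0, 4.0, 2.0], [2.0, 2.0, 16.0]]) / 30.0
        Kes = Ke[None] / h[:, None, None]
        Mes = Me[None] * h[:, None, None]

    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    nb = cell_dofs.shape[1]
    rows = np.repeat(cell_dofs, nb, axis=1).ravel()
    cols = np.tile(cell_dofs, (1, nb)).ravel()

    def asm(elems):
        return sp.coo_matrix((elems.ravel(), (rows, cols)), shape=(nd, nd)).tocsr()

    betas = np.stack([problem.subdomains[s][1] for s in cell_sub])  # (nc,n,n)
    blocks = [[None] * n for _ in range(n)]
    for i in range(n):
        blocks[i][i] = asm(problem.k[i] * Kes)
    for i in range(n):
        for j in range(i + 1, n):
            bij = betas[:, i, j]
            if np.any(bij != 0):
                Mij = asm(bij[:, None, None] * Mes)
                blocks[i][i] = blocks[i][i] + Mij
                blocks[j][j] = blocks[j][j] + Mij
                blocks[i][j] = -Mij
                blocks[j][i] = -Mij
    A = sp.bmat(blocks, format="csr")
    b = np.zeros(n * nd)

    x_full = np.zeros(n * nd)
    fixed = np.zeros(n * nd, dtype=bool)
    end_node = {0: 0, 1: len(verts) - 1}
    for bc in problem.bcs:
        g = bc.comp * nd + end_node[bc.end]
        if bc.kind == "dirichlet":
            fixed[g] = True
            x_full[g] = bc.value
        else:
            # natural BC: k dp/dx * n = k * value * n contributes k*b*t(x_b)
            sign = -1.0 if bc.end == 0 else 1.0
            b[g] += sign * problem.k[bc.comp] * bc.value
    free = ~fixed
    b = b - A @ x_full
    x_full[free] = spla.spsolve(A[free][:, free].tocsc(), b[free])
    p = x_full.reshape(n, nd)[:, :len(verts)]
    return verts, p


def fe_averages(problem: ColumnProblem, n_cells: int = 400) -> ColumnAverages:
    """Layer-averaged pressures/perfusion from the 1D FE solution
    (trapezoidal integration on the FE nodes)."""
    verts, p = solve_column_fe(problem, n_cells=n_cells, order=1)
    bp = problem.breakpoints
    n = problem.n
    n_sub = len(problem.subdomains)
    p_sub = np.zeros((n_sub, n))
    F_sub = np.zeros(n_sub)
    lengths = np.diff(bp)
    for s in range(n_sub):
        mask = (verts >= bp[s] - 1e-12) & (verts <= bp[s + 1] + 1e-12)
        xs = verts[mask]
        for i in range(n):
            p_sub[s, i] = np.trapezoid(p[i][mask], xs) / lengths[s]
        b12 = problem.subdomains[s][1][0, 1]
        F_sub[s] = b12 * (p_sub[s, 0] - p_sub[s, 1])
    w = lengths / lengths.sum()
    return ColumnAverages(pressure=w @ p_sub, pressure_sub=p_sub,
                          F_total=float(perfusion_to_clinical(w @ F_sub)),
                          F_sub=perfusion_to_clinical(F_sub))
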