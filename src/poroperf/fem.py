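"""Coupled multi-compartment Darcy finite elements on tetrahedra.

Solves the steady coupled system

    div(K_i grad p_i) = sum_j beta_ij (p_i - p_j) - S_i,   i = 1..n,

with continuous P1 or P2 Lagrange elements (Bubnov-Galerkin).  Permeability
tensors K_i, coupling coefficients beta_ij and sources S_i are piecewise
constant per cell (sources may also be coordinate functions).  Dirichlet
conditions are enforced by symmetric elimination, periodic conditions by
DoF identification across translated box faces, and Neumann data enters
the load vector through boundary-facet quadrature.

The assembled block matrix is symmetric positive definite whenever beta is
symmetric and every coupling-connected group of compartments carries at
least one Dirichlet surface; the direct path factorises with SuperLU and
the iterative path runs preconditioned CG/BiCGSTAB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import roots_jacobi

from .meshing import Mesh, MeshError, TET_FACES

__all__ = [
    "FESpace", "FieldSpec", "BCSpec", "PressureSolution", "LinearSystem",
    "assemble", "solve", "probe", "l2_error", "tet_quadrature", "tri_quadrature",
    "WellPosednessError", "SolverError",
]


class WellPosednessError(ValueError):
    """Raised when the boundary-condition set leaves the system singular."""


class SolverError(RuntimeError):
    """Raised when the linear solver fails; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


# -- quadrature (Stroud conical products) ------------------------------------

def _gauss01(n, alpha):
    """Gauss-Jacobi rule for weight (1-t)^alpha on [0, 1]."""
    x, w = roots_jacobi(n, alpha, 0.0)
    return (x + 1.0) / 2.0, w / 2.0 ** (alpha + 1)


def tet_quadrature(degree: int):
    """Points/weights integrating polynomials of total ``degree`` exactly
    over the reference tetrahedron {xi,eta,zeta >= 0, xi+eta+zeta <= 1}."""
    n = degree // 2 + 1
    a, wa = _gauss01(n, 2.0)
    b, wb = _gauss01(n, 1.0)
    c, wc = _gauss01(n, 0.0)
    A, B, C = np.meshgrid(a, b, c, indexing="ij")
    WA, WB, WC = np.meshgrid(wa, wb, wc, indexing="ij")
    xi = A.ravel()
    eta = (B * (1 - A)).ravel()
    zeta = (C * (1 - A) * (1 - B)).ravel()
    w = (WA * WB * WC).ravel()
    return np.column_stack([xi, eta, zeta]), w


def tri_quadrature(degree: int):
    """Conical-product rule on the reference triangle (area 1/2)."""
    n = degree // 2 + 1
    a, wa = _gauss01(n, 1.0)
    b, wb = _gauss01(n, 0.0)
    A, B = np.meshgrid(a, b, indexing="ij")
    WA, WB = np.meshgrid(wa, wb, indexing="ij")
    xi = A.ravel()
    eta = (B * (1 - A)).ravel()
    return np.column_stack([xi, eta]), (WA * WB).ravel()


#: quadrature degree used for error norms and polynomial load terms
ERROR_QUAD_DEGREE = 10

_EDGE_VERTICES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def shape_functions(order: int, pts: np.ndarray):
    """Values and reference gradients of the tet Lagrange basis.

    Returns ``N`` of shape (nq, nb) and ``dN`` of shape (nq, nb, 3) for
    barycentric-ordered nodes: 4 vertices, then (for P2) the 6 edge
    midpoints in the order (01, 02, 03, 12, 13, 23).
    """
    pts = np.atleast_2d(pts)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.stack([1 - xi - eta - zeta, xi, eta, zeta], axis=1)  # (nq, 4)
    dlam = np.array([[-1.0, -1.0, -1.0],
                     [1.0, 0.0, 0.0],
                     [0.0, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])
    if order == 1:
        N = lam
        dN = np.broadcast_to(dlam, (len(pts), 4, 3)).copy()
        return N, dN
    if order != 2:
        raise ValueError("only P1 and P2 elements are supported")
    nq = len(pts)
    N = np.empty((nq, 10))
    dN = np.empty((nq, 10, 3))
    for v in range(4):
        N[:, v] = lam[:, v] * (2 * lam[:, v] - 1)
        dN[:, v, :] = (4 * lam[:, v, None] - 1) * dlam[v]
    for e, (i, j) in enumerate(_EDGE_VERTICES):
        N[:, 4 + e] = 4 * lam[:, i] * lam[:, j]
        dN[:, 4 + e, :] = 4 * (lam[:, i, None] * dlam[j] + lam[:, j, None] * dlam[i])
    return N, dN


# -- finite element space -----------------------------------------------------

class FESpace:
    """Scalar continuous Lagrange space (P1/P2) on a tetrahedral mesh."""

    def __init__(self, mesh: Mesh, order: int):
        if order not in (1, 2):
            raise ValueError("element order must be 1 or 2")
        self.mesh = mesh
        self.order = order
        nv = mesh.n_vertices
        if order == 1:
            self.cell_dofs = mesh.cells.copy()
            self.dof_coords = mesh.vertices.copy()
            self.edge_index = None
        else:
            edges = np.concatenate([mesh.cells[:, e] for e in _EDGE_VERTICES])
            key = np.sort(edges, axis=1)
            uniq, inv = np.unique(key, axis=0, return_inverse=True)
            inv = inv.reshape(6, mesh.n_cells).T
            self.cell_dofs = np.hstack([mesh.cells, nv + inv])
            self.dof_coords = np.vstack([mesh.vertices, mesh.vertices[uniq].mean(axis=1)])
            self.edge_index = {tuple(e): nv + i for i, e in enumerate(map(tuple, uniq))}
        self.n_dofs = len(self.dof_coords)
        # affine geometry
        v = mesh.vertices[mesh.cells]
        J = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)      # (nc, 3 phys, 3 ref)
        self.detJ = np.linalg.det(J)
        self.Jinv = np.linalg.inv(J)                    # (nc, 3 ref, 3 phys)
        self.cell_origin = v[:, 0]

    # -- dof location ---------------------------------------------------------

    def facet_dofs(self, facets: np.ndarray) -> np.ndarray:
        """Unique DoF indices supported on the given boundary triangles."""
        dofs = set(np.unique(facets).tolist())
        if self.order == 2:
            for tri in facets:
                for i, j in ((0, 1), (0, 2), (1, 2)):
                    a, b = sorted((tri[i], tri[j]))
                    dofs.add(self.edge_index[(a, b)])
        return np.array(sorted(dofs), dtype=int)

    def map_to_reference(self, cell: int, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.cell_origin[cell]) @ self.Jinv[cell].T

    def map_from_reference(self, cells, ref_pts: np.ndarray) -> np.ndarray:
        v = self.mesh.vertices[self.mesh.cells[cells]]
        lam = np.concatenate([1 - ref_pts.sum(axis=1, keepdims=True), ref_pts], axis=1)
        return np.einsum("qa,cad->cqd", lam, v) if v.ndim == 3 else lam @ v


# -- elementary matrices -------------------------------------------------------

_CHUNK = 40000


def stiffness_matrix(space: FESpace, K_cells) -> sp.csr_matrix:
    """Global matrix of ∫ (K grad u) · (grad v) dΩ, K piecewise constant."""
    mesh, order = space.mesh, space.order
    K = _expand_tensor(K_cells, mesh.n_cells)
    pts, w = tet_quadrature(2 * order)
    _, dN = shape_functions(order, pts)
    nb = dN.shape[1]
    rows, cols, vals = [], [], []
    for s in range(0, mesh.n_cells, _CHUNK):
        sl = slice(s, min(s + _CHUNK, mesh.n_cells))
        g = np.einsum("qbr,crd->cqbd", dN, space.Jinv[sl])
        Kg = np.einsum("cde,cqbe->cqbd", K[sl], g)
        Ae = np.einsum("q,cqad,cqbd->cab", w, g, Kg) * space.detJ[sl, None, None]
        cd = space.cell_dofs[sl]
        rows.append(np.repeat(cd, nb, axis=1).ravel())
        cols.append(np.tile(cd, (1, nb)).ravel())
        vals.append(Ae.ravel())
    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(space.n_dofs, space.n_dofs))
    return A.tocsr()


def mass_matrix(space: FESpace, w_cells=None) -> sp.csr_matrix:
    """Global matrix of ∫ w u v dΩ with piecewise-constant weight w."""
    mesh, order = space.mesh, space.order
    wc = np.ones(mesh.n_cells) if w_cells is None else np.broadcast_to(
        np.asarray(w_cells, dtype=float), (mesh.n_cells,))
    pts, w = tet_quadrature(2 * order)
    N, _ = shape_functions(order, pts)
    Me_ref = np.einsum("q,qa,qb->ab", w, N, N)
    nb = N.shape[1]
    scale = wc * space.detJ
    Ae = Me_ref[None, :, :] * scale[:, None, None]
    cd = space.cell_dofs
    A = sp.coo_matrix((Ae.ravel(),
                       (np.repeat(cd, nb, axis=1).ravel(), np.tile(cd, (1, nb)).ravel())),
                      shape=(space.n_dofs, space.n_dofs))
    return A.tocsr()


def load_vector(space: FESpace, f: Callable, degree: int = ERROR_QUAD_DEGREE) -> np.ndarray:
    """Assemble ∫ f v dΩ for a coordinate function f (vectorised on (m,3))."""
    pts, w = tet_quadrature(degree)
    N, _ = shape_functions(space.order, pts)
    b = np.zeros(space.n_dofs)
    nc = space.mesh.n_cells
    for s in range(0, nc, _CHUNK):
        sl = slice(s, min(s + _CHUNK, nc))
        cells = np.arange(sl.start, sl.stop)
        phys = space.map_from_reference(cells, pts)          # (c, q, 3)
        fv = np.asarray(f(phys.reshape(-1, 3))).reshape(len(cells), -1)
        be = np.einsum("q,cq,qa->ca", w, fv, N) * space.detJ[sl, None]
        np.add.at(b, space.cell_dofs[sl].ravel(), be.ravel())
    return b


def _facet_cells(mesh: Mesh):
    """Owning cell of every boundary facet (dict keyed by sorted vertex triple)."""
    faces = mesh.cells[:, TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    owner = {}
    cell_ids = np.repeat(np.arange(mesh.n_cells), 4)
    for k, c in zip(map(tuple, key), cell_ids):
        owner.setdefault(k, []).append(c)
    return {k: v[0] for k, v in owner.items() if len(v) == 1}


def neumann_load(space: FESpace, facets: np.ndarray, value, degree: int = 6) -> np.ndarray:
    """Assemble ∫_Γ b v dΓ over the given boundary triangles.

    ``value`` is a constant or a coordinate function; the sign convention is
    that of the natural boundary term (K grad p)·n = b.
    """
    mesh = space.mesh
    owner = _facet_cells(mesh)
    rpts, rw = tri_quadrature(degree)
    b = np.zeros(space.n_dofs)
    for tri in facets:
        key = tuple(sorted(tri))
        if key not in owner:
            raise MeshError("facet is not on the mesh boundary")
        cell = owner[key]
        p = mesh.vertices[tri]
        phys = (p[0][None, :] + rpts[:, :1] * (p[1] - p[0])[None, :]
                + rpts[:, 1:2] * (p[2] - p[0])[None, :])
        area2 = np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        ref = space.map_to_reference(cell, phys)
        N, _ = shape_functions(space.order, ref)
        if callable(value):
            fv = np.asarray(value(phys), dtype=float)
        else:
            fv = np.full(len(phys), float(value))
        contrib = np.einsum("q,q,qa->a", rw, fv, N) * area2
        np.add.at(b, space.cell_dofs[cell], contrib)
    return b


def _expand_tensor(K, nc):
    K = np.asarray(K, dtype=float)
    if K.ndim == 0:
        return np.broadcast_to(K * np.eye(3), (nc, 3, 3))
    if K.shape == (3, 3):
        return np.broadcast_to(K, (nc, 3, 3))
    if K.shape == (nc,):
        return K[:, None, None] * np.eye(3)[None]
    if K.shape == (nc, 3, 3):
        return K
    raise ValueError(f"cannot interpret permeability of shape {K.shape}")


# -- problem specification -----------------------------------------------------

@dataclass
class FieldSpec:
    """Coefficients of the coupled system on a given mesh.

    ``K``: per-compartment permeability (scalar, 3x3, (nc,) or (nc,3,3)).
    ``beta``: (n,n) constant matrix or (nc,n,n) per-cell coupling.
    ``S``: per-compartment source coordinate functions (or None).
    """

    K: Sequence
    beta: np.ndarray
    S: Optional[Sequence[Optional[Callable]]] = None

    @property
    def n_compartments(self) -> int:
        return len(self.K)

    def beta_cells(self, nc: int) -> np.ndarray:
        beta = np.asarray(self.beta, dtype=float)
        n = self.n_compartments
        if beta.shape == (n, n):
            beta = np.broadcast_to(beta, (nc, n, n))
        if beta.shape != (nc, n, n):
            raise ValueError("beta must be (n,n) or (nc,n,n)")
        if not np.allclose(beta, np.swapaxes(beta, 1, 2)):
            raise ValueError("coupling matrix must be symmetric")
        return beta

    @staticmethod
    def from_params(internal, mesh: Mesh, K_override=None) -> "FieldSpec":
        """Isotropic fields from an InternalParams bundle, with GREY/WHITE
        coupling looked up from the mesh's cell labels."""
        from .meshing import GREY
        nc = mesh.n_cells
        beta = np.where((mesh.cell_labels == GREY)[:, None, None],
                        internal.beta_grey[None], internal.beta_white[None])
        K = K_override if K_override is not None else list(internal.k)
        return FieldSpec(K=K, beta=beta)


@dataclass
class BCSpec:
    """Boundary conditions of the coupled problem.

    ``dirichlet``/``neumann``: lists of (compartment index, facet label,
    value), where value is a constant or a coordinate function on (m,3)
    points.  ``periodic_axes`` lists coordinate axes whose min/max box faces
    are identified (structured meshes only).
    """

    dirichlet: list = field(default_factory=list)
    neumann: list = field(default_factory=list)
    periodic_axes: tuple = ()

    def validate(self, n_comp: int) -> None:
        seen = {}
        for comp, label, _ in self.dirichlet:
            seen.setdefault(comp, set()).add(label)
        for comp, label, _ in self.neumann:
            if label in seen.get(comp, ()):
                raise WellPosednessError(
                    f"label {label} carries both Dirichlet and Neumann data "
                    f"for compartment {comp}")
        for comp, _, _ in self.dirichlet + self.neumann:
            if not 0 <= comp < n_comp:
                raise WellPosednessError(f"compartment index {comp} out of range")


def _check_well_posed(bcs: BCSpec, beta_cells: np.ndarray, n: int) -> None:
    """Every coupling-connected compartment group needs one Dirichlet patch."""
    coupled = (np.abs(beta_cells).max(axis=0) > 0)
    comp_of = np.arange(n)
    for i in range(n):
        for j in range(n):
            if coupled[i, j]:
                root = min(comp_of[i], comp_of[j])
                comp_of[comp_of == comp_of[i]] = root
                comp_of[comp_of == comp_of[j]] = root
    has_dbc = set(comp for comp, _, _ in bcs.dirichlet)
    for group in np.unique(comp_of):
        members = np.where(comp_of == group)[0]
        if not any(m in has_dbc for m in members):
            raise WellPosednessError(
                f"compartment group {members.tolist()} has no Dirichlet surface: "
                "the pure-Neumann problem is singular")


# -- constraint handling -------------------------------------------------------

def _periodic_master_map(space: FESpace, axes) -> np.ndarray:
    """Map each DoF to its periodic master by canonical coordinates."""
    coords = space.dof_coords.copy()
    lo = space.mesh.vertices.min(axis=0)
    hi = space.mesh.vertices.max(axis=0)
    scale = max(1.0, np.abs(np.concatenate([lo, hi])).max())
    for ax in axes:
        on_hi = np.abs(coords[:, ax] - hi[ax]) < 1e-10 * scale
        coords[on_hi, ax] = lo[ax]
    key = np.round(coords / (1e-8 * scale)).astype(np.int64)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    if len(uniq) == space.n_dofs:
        # nothing identified although axes were requested -> geometry mismatch
        if axes:
            raise WellPosednessError("periodic faces do not match under translation")
    order = np.argsort(inv, kind="stable")
    first = np.zeros(len(uniq), dtype=int)
    seen = np.zeros(len(uniq), dtype=bool)
    for d in order:
        g = inv[d]
        if not seen[g]:
            first[g] = d
            seen[g] = True
    return first[inv]


def _reduction_matrix(master: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse R with R[dof, reduced(master)] = 1; returns (R, reduced ids of masters)."""
    masters = np.unique(master)
    red_id = -np.ones(len(master), dtype=int)
    red_id[masters] = np.arange(len(masters))
    R = sp.csr_matrix((np.ones(len(master)), (np.arange(len(master)), red_id[master])),
                      shape=(len(master), len(masters)))
    return R, red_id


# -- assembled system ----------------------------------------------------------

@dataclass
class LinearSystem:
    space: FESpace
    n_comp: int
    A: sp.csr_matrix                 # reduced (periodic-merged) block matrix
    b: np.ndarray
    R: sp.csr_matrix                 # full-block <- reduced-block expansion
    dirichlet_idx: np.ndarray        # reduced indices
    dirichlet_val: np.ndarray
    n_reduced_scalar: int = 0        # reduced DoFs per compartment

    @property
    def n_dofs(self) -> int:
        return self.n_comp * self.space.n_dofs


def assemble(mesh: Mesh, fields: FieldSpec, bcs: BCSpec, order: int = 1) -> LinearSystem:
    """Assemble the coupled block system with all constraints applied."""
    n = fields.n_compartments
    bcs.validate(n)
    space = FESpace(mesh, order)
    nd = space.n_dofs
    beta_cells = fields.beta_cells(mesh.n_cells)
    _check_well_posed(bcs, beta_cells, n)

    for i in range(n):
        Kc = _expand_tensor(fields.K[i], mesh.n_cells)
        eig = np.linalg.eigvalsh(0.5 * (Kc + np.swapaxes(Kc, 1, 2)))
        if eig.min() < -1e-12 * max(1.0, eig.max()):
            raise ValueError(f"permeability of compartment {i} is indefinite")

    blocks = [[None] * n for _ in range(n)]
    for i in range(n):
        blocks[i][i] = stiffness_matrix(space, fields.K[i])
    # coupling (reaction) blocks; beta symmetric so M_ij = M_ji
    for i in range(n):
        for j in range(i + 1, n):
            bij = beta_cells[:, i, j]
            if np.any(bij != 0):
                M = mass_matrix(space, bij)
                blocks[i][i] = blocks[i][i] + M
                blocks[j][j] = blocks[j][j] + M
                blocks[i][j] = -M
                blocks[j][i] = -M
    A_full = sp.bmat(blocks, format="csr")

    b_full = np.zeros(n * nd)
    if fields.S is not None:
        for i, Si in enumerate(fields.S):
            if Si is not None:
                b_full[i * nd:(i + 1) * nd] = load_vector(space, Si)
    for comp, label, value in bcs.neumann:
        if callable(value) or value != 0.0:
            facets = mesh.facets_with_label(label)
            b_full[comp * nd:(comp + 1) * nd] += neumann_load(space, facets, value)

    # periodic identification (same scalar map for every compartment)
    master = _periodic_master_map(space, bcs.periodic_axes) if bcs.periodic_axes \
        else np.arange(nd)
    R1, red_id = _reduction_matrix(master)
    R = sp.block_diag([R1] * n, format="csr")
    A = (R.T @ A_full @ R).tocsr()
    b = R.T @ b_full
    n_red1 = R1.shape[1]

    # Dirichlet data in reduced numbering
    dir_idx, dir_val = [], []
    for comp, label, value in bcs.dirichlet:
        facets = mesh.facets_with_label(label)
        dofs = space.facet_dofs(facets)
        coords = space.dof_coords[dofs]
        vals = (np.asarray(value(coords), dtype=float) if callable(value)
                else np.full(len(dofs), float(value)))
        ridx = red_id[master[dofs]] + comp * n_red1
        dir_idx.append(ridx)
        dir_val.append(vals)
    if dir_idx:
        dir_idx = np.concatenate(dir_idx)
        dir_val = np.concatenate(dir_val)
        dir_idx, keep = np.unique(dir_idx, return_index=True)
        dir_val = dir_val[keep]
    else:
        dir_idx = np.array([], dtype=int)
        dir_val = np.array([])

    return LinearSystem(space, n, A, b, R, dir_idx, dir_val, n_red1)


@dataclass
class PressureSolution:
    """Per-compartment FE coefficient vectors on a mesh at a given order."""

    mesh: Mesh
    order: int
    space: FESpace = field(repr=False)
    coeffs: np.ndarray               # (n_comp, n_dofs)

    @property
    def n_compartments(self) -> int:
        return len(self.coeffs)

    def vertex_values(self, comp: int) -> np.ndarray:
        return self.coeffs[comp][:self.mesh.n_vertices]


def solve(system: LinearSystem, method: str = "direct", rtol: float = 1e-10,
          maxiter: int = 20000) -> PressureSolution:
    """Solve the assembled system; 'direct' (SuperLU) or 'iterative' (CG,
    falling back to BiCGSTAB) with an incomplete-LU preconditioner."""
    A, b = system.A, system.b.copy()
    nred = A.shape[0]
    free = np.ones(nred, dtype=bool)
    free[system.dirichlet_idx] = False
    x = np.zeros(nred)
    x[system.dirichlet_idx] = system.dirichlet_val
    b = b - A @ x
    A_ff = A[free][:, free].tocsc()
    b_f = b[free]

    if method == "direct":
        try:
            # the block system is structurally symmetric: symmetric-mode
            # minimum-degree ordering roughly halves the factorisation time
            lu = spla.splu(A_ff, permc_spec="MMD_AT_PLUS_A",
                           options=dict(SymmetricMode=True))
        except RuntimeError as exc:
            raise SolverError(f"direct factorisation failed: {exc}") from exc
        x_f = lu.solve(b_f)
        if not np.all(np.isfinite(x_f)):
            raise SolverError("direct solve produced non-finite values "
                              "(singular system, e.g. pure-Neumann problem)")
    elif method == "iterative":
        # compartment-block-Jacobi preconditioner: exact factorisation of
        # each per-compartment diagonal block (cheap -- the blocks never
        # mix compartments), CG over the coupled system
        residuals = []
        norm_b = np.linalg.norm(b_f) or 1.0

        def cb(xk):
            residuals.append(np.linalg.norm(b_f - A_ff @ xk) / norm_b)

        comp_of = np.repeat(np.arange(system.n_comp), system.n_reduced_scalar)[free]
        try:
            blocks = []
            for c in range(system.n_comp):
                idx = np.flatnonzero(comp_of == c)
                lu_c = spla.splu(A_ff[idx][:, idx].tocsc(),
                                 permc_spec="MMD_AT_PLUS_A",
                                 options=dict(SymmetricMode=True))
                blocks.append((idx, lu_c))

            def prec(v):
                out = np.empty_like(v)
                for idx, lu_c in blocks:
                    out[idx] = lu_c.solve(v[idx])
                return out
            M = spla.LinearOperator(A_ff.shape, prec)
        except RuntimeError as exc:
            raise SolverError(f"preconditioner setup failed: {exc}") from exc
        x_f, info = spla.cg(A_ff, b_f, rtol=rtol, atol=0.0, M=M,
                            maxiter=maxiter, callback=cb)
        if info != 0:
            x_f, info = spla.bicgstab(A_ff, b_f, rtol=rtol, atol=0.0, M=M,
                                      maxiter=maxiter)
        if info != 0:
            raise SolverError(f"iterative solver did not converge (info={info})",
                              residuals=residuals)
    else:
        raise ValueError("method must be 'direct' or 'iterative'")

    x[free] = x_f
    full = system.R @ x
    coeffs = full.reshape(system.n_comp, system.space.n_dofs)
    return PressureSolution(system.space.mesh, system.space.order,
                            system.space, coeffs)


# -- point evaluation and error norms -----------------------------------------

def locate_cell(space: FESpace, point, tol: float = 1e-10) -> int:
    """Index of a cell whose closure contains ``point`` (interior side for
    boundary points: any containing cell evaluates the one-sided basis)."""
    p = np.asarray(point, dtype=float)
    ref = np.einsum("crd,d->cr", space.Jinv, p) - \
        np.einsum("crd,cd->cr", space.Jinv, space.cell_origin)
    lam0 = 1 - ref.sum(axis=1)
    inside = (ref.min(axis=1) >= -tol) & (lam0 >= -tol)
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        raise ValueError(f"point {p} is outside the mesh")
    return int(idx[0])


def probe(solution: PressureSolution, point, comp: int, derivative: str = "value"):
    """Evaluate p_i (scalar) or grad p_i (3-vector) at a physical point."""
    space = solution.space
    cell = locate_cell(space, point)
    ref = space.map_to_reference(cell, np.asarray(point, dtype=float))
    N, dN = shape_functions(space.order, ref)
    coeffs = solution.coeffs[comp][space.cell_dofs[cell]]
    if derivative == "value":
        return float(N[0] @ coeffs)
    if derivative == "gradient":
        g = np.einsum("br,rd->bd", dN[0], space.Jinv[cell])
        return coeffs @ g
    raise ValueError("derivative must be 'value' or 'gradient'")


def evaluate(solution: PressureSolution, points: np.ndarray, comp: int) -> np.ndarray:
    """Values of compartment ``comp`` at an array of points (slow path)."""
    return np.array([probe(solution, p, comp) for p in np.atleast_2d(points)])


def l2_error(solution: PressureSolution, exact: Sequence[Callable],
             degree: int = ERROR_QUAD_DEGREE) -> float:
    """Root-sum-square L2 norm of (p_i - p_i_exact) over all compartments."""
    space = solution.space
    pts, w = tet_quadrature(degree)
    N, _ = shape_functions(space.order, pts)
    total = 0.0
    nc = space.mesh.n_cells
    for s in range(0, nc, _CHUNK):
        cells = np.arange(s, min(s + _CHUNK, nc))
        phys = space.map_from_reference(cells, pts)
        cd = space.cell_dofs[cells]
        for i, pex in enumerate(exact):
            fe = solution.coeffs[i][cd] @ N.T                       # (c, q)
            ex = np.asarray(pex(phys.reshape(-1, 3))).reshape(len(cells), -1)
            total += float(np.sum(((fe - ex) ** 2 * w[None, :]).sum(axis=1)
                                  * space.detJ[cells]))
    return float(np.sqrt(total))
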