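"""Velocity, flow-rate and perfusion post-processing.

The Darcy velocity of compartment i is u_i = -K_i grad p_i.  Because the
pressure solve is H1-conforming and not conservative, the surface flow
rate

    Q_Gamma = -int_Gamma u_1 . n dGamma            (inflow positive)

and the volumetric perfusion flow

    Q_Omega = int_Omega beta12 (p1 - p2) dOmega

differ by a discretisation error; their relative difference (in %) is the
mass-conservation diagnostic.  Velocities are available cell-wise at their
natural order (dP0 for P1 pressures, dP1 for P2) or L2-projected onto a
continuous Lagrange space via a global mass-matrix solve.

Perfusion is F = beta12 (p1 - p2); infarcted tissue is classified
cell-by-cell as a perfusion drop of more than 70% against the healthy
baseline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import scipy.sparse.linalg as spla

from . import fem
from .fem import (BCSpec, FESpace, PressureSolution, WellPosednessError,
                  _expand_tensor, _facet_cells, mass_matrix, shape_functions,
                  tet_quadrature, tri_quadrature)
from .meshing import Mesh, MeshError
from .params import perfusion_to_clinical

__all__ = ["VelocityField", "darcy_velocity", "surface_flux", "volumetric_flow",
           "FluxReport", "flux_report", "cell_perfusion", "infarct_fraction",
           "make_occlusion_bcs", "uniform_inlet_value", "field_stats"]


@dataclass
class VelocityField:
    """u = -K grad p for one compartment.

    ``kind`` is 'cellwise' (natural discontinuous representation evaluated
    from the pressure gradient) or 'nodal' (L2 projection onto continuous
    P1/P2, coefficients per DoF).
    """

    space: FESpace
    comp: int
    K_cells: np.ndarray                       # (nc, 3, 3)
    kind: str
    pressure: Optional[PressureSolution] = None
    nodal: Optional[np.ndarray] = None        # (n_dofs, 3) for kind='nodal'
    proj_space: Optional[FESpace] = None

    def eval_in_cells(self, cells: np.ndarray, ref_pts: np.ndarray) -> np.ndarray:
        """Velocity at reference points of given cells, shape (nc, nq, 3)."""
        if self.kind == "cellwise":
            space = self.space
            _, dN = shape_functions(space.order, ref_pts)
            cd = space.cell_dofs[cells]
            coeffs = self.pressure.coeffs[self.comp][cd]          # (c, nb)
            g = np.einsum("qbr,crd->cqbd", dN, space.Jinv[cells])
            grad = np.einsum("cb,cqbd->cqd", coeffs, g)
            return -np.einsum("cde,cqe->cqd", self.K_cells[cells], grad)
        space = self.proj_space
        N, _ = shape_functions(space.order, ref_pts)
        vals = self.nodal[space.cell_dofs[cells]]                 # (c, nb, 3)
        return np.einsum("qb,cbd->cqd", N, vals)

    def cell_average(self) -> np.ndarray:
        """(nc, 3) cell-mean velocity (exact for the natural representation
        of P1 pressures, quadrature mean otherwise)."""
        pts, w = tet_quadrature(2)
        cells = np.arange(self.space.mesh.n_cells)
        v = self.eval_in_cells(cells, pts)
        return np.einsum("q,cqd->cd", w, v) / w.sum()


def darcy_velocity(solution: PressureSolution, comp: int, K,
                   target_order: Optional[int] = None) -> VelocityField:
    """Velocity of one compartment, natural or projected representation.

    ``target_order`` None keeps the natural cell-wise representation
    (dP0/dP1); 1 or 2 L2-projects onto the continuous Lagrange space of
    that order through a global mass-matrix solve.
    """
    mesh = solution.mesh
    K_cells = _expand_tensor(K, mesh.n_cells)
    natural = VelocityField(solution.space, comp, K_cells, "cellwise",
                            pressure=solution)
    if target_order is None:
        return natural
    if target_order not in (1, 2):
        raise ValueError("target order must be None, 1 or 2")
    proj_space = solution.space if target_order == solution.order \
        else FESpace(mesh, target_order)
    M = mass_matrix(proj_space)
    deg = 2 * max(solution.order, target_order)
    pts, w = tet_quadrature(deg)
    N, _ = shape_functions(target_order, pts)
    cells = np.arange(mesh.n_cells)
    v = natural.eval_in_cells(cells, pts)                     # (c, q, 3)
    be = np.einsum("q,cqd,qa->cad", w, v, N) * proj_space.detJ[:, None, None]
    b = np.zeros((proj_space.n_dofs, 3))
    np.add.at(b, proj_space.cell_dofs.ravel(), be.reshape(-1, 3))
    lu = spla.splu(M.tocsc())
    nodal = np.column_stack([lu.solve(b[:, d]) for d in range(3)])
    return VelocityField(solution.space, comp, K_cells, "nodal",
                         nodal=nodal, proj_space=proj_space)


def project_nodal_velocity(space_order: int, mesh: Mesh, nodal: np.ndarray,
                           K_cells=None) -> VelocityField:
    """Wrap an already-nodal vector field (used in projector tests)."""
    space = FESpace(mesh, space_order)
    return VelocityField(space, 0, _expand_tensor(np.eye(3), mesh.n_cells),
                         "nodal", nodal=nodal, proj_space=space)


def surface_flux(velocity: VelocityField, mesh: Mesh, labels=None,
                 degree: int = 4) -> dict:
    """Inflow -int u.n dGamma per boundary label (and 'total').

    ``labels`` defaults to every label present on the mesh boundary.
    """
    if labels is None:
        labels = sorted(set(mesh.facet_labels.tolist()))
    owner = _facet_cells(mesh)
    rpts, rw = tri_quadrature(degree)
    out = {}
    for label in labels:
        facets = mesh.facets_with_label(label)
        total = 0.0
        for tri in facets:
            cell = owner[tuple(sorted(tri))]
            p = mesh.vertices[tri]
            e1, e2 = p[1] - p[0], p[2] - p[0]
            nvec = np.cross(e1, e2)                 # |nvec| = 2*area
            # orient outward: away from the cell centroid
            cent_cell = mesh.vertices[mesh.cells[cell]].mean(axis=0)
            if np.dot(nvec, p.mean(axis=0) - cent_cell) < 0:
                nvec = -nvec
            phys = p[0] + rpts[:, :1] * e1 + rpts[:, 1:2] * e2
            ref = velocity.space.map_to_reference(cell, phys)
            v = velocity.eval_in_cells(np.array([cell]), ref)[0]
            total += -np.einsum("q,qd,d->", rw, v, nvec)
        out[label] = float(total)
    out["total"] = float(sum(v for k, v in out.items() if k != "total"))
    return out


def volumetric_flow(solution: PressureSolution, beta_cells: np.ndarray,
                    region_of: Optional[np.ndarray] = None) -> tuple:
    """Q_Omega = int beta12 (p1-p2) dOmega, plus per-region perfusion means.

    ``beta_cells``: (nc, n, n) coupling field; ``region_of`` defaults to the
    mesh's cell labels.  Returns (Q_omega, {region: <F> in ml/min/100ml}).
    """
    mesh = solution.mesh
    F_cells = cell_perfusion(solution, beta_cells)
    vol = mesh.cell_volumes()
    Q = float(np.sum(F_cells * vol))
    regions = mesh.cell_labels if region_of is None else region_of
    averages = {}
    for r in np.unique(regions):
        m = regions == r
        averages[int(r)] = float(perfusion_to_clinical(
            np.sum(F_cells[m] * vol[m]) / vol[m].sum()))
    return Q, averages


def cell_perfusion(solution: PressureSolution, beta_cells: np.ndarray) -> np.ndarray:
    """Cell-averaged perfusion F = beta12 (p1 - p2), shape (nc,), in 1/s."""
    space = solution.space
    pts, w = tet_quadrature(2 * space.order)
    N, _ = shape_functions(space.order, pts)
    cd = space.cell_dofs
    p1 = solution.coeffs[0][cd] @ N.T
    p2 = solution.coeffs[1][cd] @ N.T
    mean = (w[None, :] * (p1 - p2)).sum(axis=1) / w.sum()
    b12 = np.asarray(beta_cells)[:, 0, 1]
    return b12 * mean


@dataclass
class FluxReport:
    """Mass-conservation diagnostic of one solve."""

    Q_gamma: float                       # surface inflow through the inlet label(s)
    Q_omega: float                       # volume-integrated perfusion
    delta_r_percent: float               # (Q_gamma - Q_omega)/Q_omega * 100
    per_label: dict = dc_field(default_factory=dict)
    region_perfusion: dict = dc_field(default_factory=dict)

    def as_dict(self):
        return {"Q_gamma": self.Q_gamma, "Q_omega": self.Q_omega,
                "delta_r_percent": self.delta_r_percent,
                "per_label": {str(k): v for k, v in self.per_label.items()},
                "region_perfusion": {str(k): v for k, v in
                                     self.region_perfusion.items()}}


def flux_report(solution: PressureSolution, beta_cells: np.ndarray, K1,
                inlet_labels, velocity_order: Optional[int] = None) -> FluxReport:
    """Combine surface and volumetric flow into the Delta_r diagnostic.

    ``inlet_labels``: boundary labels through which arteriole blood enters
    (Q_gamma sums these); ``velocity_order`` picks natural (None) or
    projected velocity for the facet integral.
    """
    vel = darcy_velocity(solution, 0, K1, target_order=velocity_order)
    per = surface_flux(vel, solution.mesh, labels=list(inlet_labels))
    Q_gamma = sum(per[label] for label in inlet_labels)
    Q_omega, region = volumetric_flow(solution, beta_cells)
    delta = (Q_gamma - Q_omega) / Q_omega * 100.0 if Q_omega != 0 else np.nan
    return FluxReport(Q_gamma=float(Q_gamma), Q_omega=float(Q_omega),
                      delta_r_percent=float(delta), per_label=per,
                      region_perfusion=region)


def infarct_fraction(healthy_F: np.ndarray, occluded_F: np.ndarray,
                     volumes: np.ndarray, threshold: float = 0.7) -> float:
    """Volume fraction with perfusion drop exceeding ``threshold``.

    Cell-averaged perfusion fields on the same mesh; a cell is infarcted
    when occluded F < (1 - threshold) * healthy F (strict inequality).
    """
    healthy_F = np.asarray(healthy_F, dtype=float)
    occluded_F = np.asarray(occluded_F, dtype=float)
    if healthy_F.shape != occluded_F.shape or len(healthy_F) != len(volumes):
        raise ValueError("perfusion fields must live on the same mesh")
    # classify on the fractional drop so that exactly-at-threshold cells
    # stay healthy regardless of floating-point representation of 1-theta
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = np.where(healthy_F > 0,
                        (healthy_F - occluded_F) / healthy_F, 0.0)
    infarcted = drop > threshold
    return float(volumes[infarcted].sum() / volumes.sum())


def make_occlusion_bcs(bcs: BCSpec, occluded_label: int,
                       arteriole: int = 0) -> BCSpec:
    """Model a feeding-artery occlusion: zero flux through its territory.

    The arteriole Dirichlet entry on ``occluded_label`` becomes a
    homogeneous Neumann entry; every other condition (including the venule
    Dirichlet on the same patch — venous drainage is not blocked by an
    arterial clot) is kept.
    """
    new = copy.deepcopy(bcs)
    hits = [e for e in new.dirichlet
            if e[0] == arteriole and e[1] == occluded_label]
    if not hits:
        raise MeshError(f"label {occluded_label} carries no arteriole "
                        "Dirichlet condition to occlude")
    new.dirichlet = [e for e in new.dirichlet if e not in hits]
    new.neumann = list(new.neumann) + [(arteriole, occluded_label, 0.0)]
    if not any(e[0] == arteriole for e in new.dirichlet):
        raise WellPosednessError(
            "occluding every inlet leaves the arteriole compartment with a "
            "pure-Neumann problem")
    return new


def uniform_inlet_value(mesh: Mesh, label: int, Q_target: float) -> float:
    """Neumann datum b = Q_target / area(label) for a uniform-velocity inlet.

    The natural boundary term is (K grad p).n = b, i.e. -u.n = b, so a
    positive b drives inflow Q_target through the patch.
    """
    facets = mesh.facets_with_label(label)
    p = mesh.vertices[facets]
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                                axis=1).sum()
    return float(Q_target / area)


def field_stats(solution: PressureSolution, beta_cells: np.ndarray) -> dict:
    """min/max/mean of arteriole pressure and perfusion (inlet-BC comparisons)."""
    vol = solution.mesh.cell_volumes()
    F = cell_perfusion(solution, beta_cells)
    p1 = solution.coeffs[0]
    return {
        "p1_min": float(p1.min()), "p1_max": float(p1.max()),
        "p1_mean": float(p1.mean()),
        "F_min": float(F.min()), "F_max": float(F.max()),
        "F_mean": float(np.sum(F * vol) / vol.sum()),
    }
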