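"""Descending-vessel orientation fields and anisotropic permeability.

Penetrating arterioles and ascending venules run from the pial surface
towards the ventricles.  Their local axis is obtained from a single scalar
Laplace (diffusion) solve: unit Dirichlet data on the source surface, zero
on the sink surface, zero flux elsewhere; the unit vector zeta is the
normalised negative gradient, taken per cell from the P1 solution (whose
cell gradient is constant).

The arteriole/venule permeability tensors are rank-1 bundles along zeta:
K_i = k_i * (zeta x zeta), i.e. the rotation of diag(0,0,k_i) into the
local frame (for a rank-1 reference tensor the full rotation and the outer
product coincide).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import fem
from .fem import BCSpec, FieldSpec, assemble, solve
from .meshing import Mesh, TET_FACES

__all__ = ["solve_orientation", "anisotropic_K"]


def solve_orientation(mesh: Mesh, source_labels, sink_labels,
                      method: str = "direct") -> np.ndarray:
    """Per-cell unit direction field from pial sources to ventricular sinks.

    Returns zeta of shape (n_cells, 3) with |zeta| = 1.  Cells where the
    potential is locally flat (gradient below 1e-14 of the field scale)
    fall back to the mean direction of their face neighbours, with a
    warning.
    """
    source_labels = list(np.atleast_1d(source_labels))
    sink_labels = list(np.atleast_1d(sink_labels))
    if not source_labels or not sink_labels:
        raise ValueError("need at least one source and one sink label")
    bcs = BCSpec(dirichlet=[(0, lab, 1.0) for lab in source_labels]
                 + [(0, lab, 0.0) for lab in sink_labels])
    fields = FieldSpec(K=[1.0], beta=np.zeros((1, 1)))
    sol = solve(assemble(mesh, fields, bcs, order=1), method=method)

    space = sol.space
    _, dN = fem.shape_functions(1, np.zeros((1, 3)))
    g = np.einsum("br,crd->cbd", dN[0], space.Jinv)
    grad = np.einsum("cb,cbd->cd", sol.coeffs[0][space.cell_dofs], g)
    zeta = -grad
    norm = np.linalg.norm(zeta, axis=1)
    scale = norm.max()
    flat = norm < 1e-14 * max(scale, 1.0)
    zeta[~flat] /= norm[~flat, None]
    if np.any(flat):
        warnings.warn(f"{flat.sum()} cells have a flat potential; using "
                      "face-neighbour average directions", RuntimeWarning,
                      stacklevel=2)
        neigh = _face_neighbours(mesh)
        for c in np.flatnonzero(flat):
            cand = [zeta[j] for j in neigh[c] if not flat[j]]
            v = np.mean(cand, axis=0) if cand else np.array([0.0, 0.0, 1.0])
            n = np.linalg.norm(v)
            zeta[c] = v / n if n > 0 else np.array([0.0, 0.0, 1.0])
    return zeta


def _face_neighbours(mesh: Mesh):
    faces = mesh.cells[:, TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    cell_ids = np.repeat(np.arange(mesh.n_cells), 4)
    shared = {}
    for k, c in zip(map(tuple, key), cell_ids):
        shared.setdefault(k, []).append(c)
    neigh = [[] for _ in range(mesh.n_cells)]
    for cs in shared.values():
        if len(cs) == 2:
            neigh[cs[0]].append(cs[1])
            neigh[cs[1]].append(cs[0])
    return neigh


def anisotropic_K(zeta: np.ndarray, k: float) -> np.ndarray:
    """Rank-1 per-cell permeability tensors K = k * zeta zeta^T.

    ``zeta`` must hold unit vectors; trace(K) = k and K zeta = k zeta in
    every cell by construction.
    """
    zeta = np.asarray(zeta, dtype=float)
    norms = np.linalg.norm(zeta, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-10):
        raise ValueError("orientation field must consist of unit vectors")
    return k * np.einsum("cd,ce->cde", zeta, zeta)
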