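"""Manufactured solutions for solver verification on the unit cube.

The assumed exact pressures mimic a cortical column driven from high
arteriole to low venule pressure,

    p1 = f(x) f(y) z^2,   p2 = f(x) f(y) f(z),   p3 = -p1,

with the quartic bump f(t) = 16 t^2 - 32 t^3 + 16 t^4 (f(0)=f(1)=0,
f(1/2)=1, f'(0)=f'(1)=0), which satisfies periodicity in x and y.
The sources that make these exact solutions of the coupled Darcy system
are generated symbolically:  S_i = sum_j beta_ij (p_i - p_j)
- div(K_i grad p_i).

Boundary conditions of the verification problem: periodic lateral faces,
Dirichlet traces of the exact solution on z=1 for the arteriole and venule
compartments, homogeneous Neumann elsewhere (the capillary compartment has
no Dirichlet surface; it is anchored through the coupling terms).

The permeability/coupling constants of the verification case are read from
a bundled YAML file so the study can be re-run under perturbed parameters;
the default case uses isotropic unit permeabilities with beta12=beta23=1.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sym
import yaml

from . import fem
from .fem import BCSpec, FieldSpec, assemble, l2_error, probe, solve
from .meshing import TOP, Mesh, build_unit_cube_mesh

__all__ = ["ManufacturedCase", "load_default_case", "ms_pressure",
           "run_convergence_study", "ConvergenceRecord"]

_X, _Y, _Z = sym.symbols("x y z")


def _bump(t):
    return 16 * t**2 - 32 * t**3 + 16 * t**4


_P_SYM = (
    _bump(_X) * _bump(_Y) * _Z**2,
    _bump(_X) * _bump(_Y) * _bump(_Z),
    -_bump(_X) * _bump(_Y) * _Z**2,
)


def _lambdify(expr) -> Callable:
    f = sym.lambdify((_X, _Y, _Z), expr, modules="numpy", cse=True)

    def call(points):
        p = np.atleast_2d(points)
        return np.broadcast_to(np.asarray(f(p[:, 0], p[:, 1], p[:, 2]),
                                          dtype=float), (len(p),)).copy()
    return call


def ms_pressure(i: int, x, y, z):
    """Exact manufactured pressure of compartment i (1-based) at (x, y, z)."""
    if i not in (1, 2, 3):
        raise ValueError("compartment index must be 1, 2 or 3")
    f = sym.lambdify((_X, _Y, _Z), _P_SYM[i - 1], modules="numpy")
    return f(x, y, z)


@dataclass
class ManufacturedCase:
    """Exact solutions plus the (K, beta) constants they are verified with."""

    K: Sequence[np.ndarray]          # three 3x3 permeability tensors
    beta: np.ndarray                 # symmetric 3x3 coupling matrix

    def __post_init__(self):
        self.K = [np.asarray(k, dtype=float).reshape(3, 3) for k in self.K]
        self.beta = np.asarray(self.beta, dtype=float).reshape(3, 3)
        if not np.allclose(self.beta, self.beta.T):
            raise ValueError("coupling matrix must be symmetric")
        self._exact = [_lambdify(p) for p in _P_SYM]
        self._sources = [_lambdify(expr) for expr in self.source_expressions()]

    @property
    def exact(self) -> list:
        """Exact pressures as vectorised coordinate functions on (m,3)."""
        return self._exact

    def exact_gradient(self, i: int, point) -> np.ndarray:
        g = [sym.diff(_P_SYM[i], v) for v in (_X, _Y, _Z)]
        return np.array([float(sym.lambdify((_X, _Y, _Z), gi)(*point)) for gi in g])

    def source_expressions(self):
        """Symbolic S_i = sum_j beta_ij (p_i - p_j) - div(K_i grad p_i)."""
        out = []
        coords = (_X, _Y, _Z)
        for i in range(3):
            pi = _P_SYM[i]
            coupling = sum(sym.Float(self.beta[i, j]) * (pi - _P_SYM[j])
                           for j in range(3))
            grad = [sym.diff(pi, v) for v in coords]
            flux = [sum(sym.Float(self.K[i][d, e]) * grad[e] for e in range(3))
                    for d in range(3)]
            div = sum(sym.diff(flux[d], coords[d]) for d in range(3))
            # kept in factored form: far cheaper to evaluate than the
            # expanded degree-12 polynomial
            out.append(coupling - div)
        return out

    @property
    def sources(self) -> list:
        """Compiled source coordinate functions on (m,3) points."""
        return self._sources

    def residual(self, points: np.ndarray) -> np.ndarray:
        """Pointwise residual of the strong form with the generated sources.

        Substitutes the exact pressures back into the governing equations:
        the result is zero up to floating-point roundoff, which is the
        independent check that sources and solutions are consistent.
        """
        coords = (_X, _Y, _Z)
        res = np.zeros((3, len(points)))
        for i in range(3):
            pi = _P_SYM[i]
            grad = [sym.diff(pi, v) for v in coords]
            flux = [sum(sym.Float(self.K[i][d, e]) * grad[e] for e in range(3))
                    for d in range(3)]
            div = sum(sym.diff(flux[d], coords[d]) for d in range(3))
            coupling = sum(sym.Float(self.beta[i, j]) * (pi - _P_SYM[j])
                           for j in range(3))
            expr = sym.expand(div - coupling + self.source_expressions()[i])
            res[i] = _lambdify(expr)(points)
        return res

    def field_spec(self, mesh: Mesh) -> FieldSpec:
        return FieldSpec(K=list(self.K), beta=self.beta, S=self.sources)

    def bcs(self) -> BCSpec:
        exact = self.exact
        return BCSpec(
            dirichlet=[(0, TOP, exact[0]), (2, TOP, exact[2])],
            periodic_axes=(0, 1),
        )


def load_default_case(path=None) -> ManufacturedCase:
    """Load the verification-case constants from the bundled YAML file."""
    if path is None:
        text = resources.files("poroperf.data").joinpath(
            "manufactured_case.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return ManufacturedCase(K=[np.array(k) for k in raw["K"]],
                            beta=np.array(raw["beta"]))


@dataclass
class ConvergenceRecord:
    """One row of the grid-convergence study."""

    ngs: float
    n_edge: int
    n_ele: int
    order: int
    n_dof: int
    l2: float
    grad_probe: float
    wall_time: float

    def as_dict(self):
        return {"NGS": self.ngs, "n_edge": self.n_edge, "n_ele": self.n_ele,
                "order": self.order, "n_dof": self.n_dof, "L2": self.l2,
                "dp1_dz_probe": self.grad_probe, "wall_time_s": self.wall_time}


def run_convergence_study(orders=(1, 2), n_edges=(2, 4, 8, 16, 32),
                          case: Optional[ManufacturedCase] = None,
                          method: str = "auto", rtol: float = 1e-11,
                          probe_point=(0.5, 0.5, 1.0)) -> list[ConvergenceRecord]:
    """Grid-convergence study of the manufactured problem.

    For each (order, n_edge) the coupled system is assembled with periodic
    lateral faces, exact-trace Dirichlet data on z=1 (arteriole and venule)
    and homogeneous Neumann data elsewhere, and the aggregated L2 error
    (root-sum-square over the three compartments) plus the dp1/dz point
    probe are recorded.  Wall times are logged but are hardware-dependent
    and never part of any assertion.
    """
    case = case or load_default_case()
    records = []
    ngs_ref = max(n_edges)
    for order in orders:
        for n_edge in n_edges:
            t0 = time.perf_counter()
            mesh = build_unit_cube_mesh(n_edge)
            system = assemble(mesh, case.field_spec(mesh), case.bcs(), order)
            row_method = method
            if method == "auto":
                # the sparse factorisation of the coupled block matrix
                # becomes memory-bound beyond ~50k unknowns; the
                # compartment-block-preconditioned CG takes over there
                row_method = "iterative" if system.n_dofs > 50_000 else "direct"
            sol = solve(system, method=row_method, rtol=rtol)
            wall = time.perf_counter() - t0
            records.append(ConvergenceRecord(
                ngs=ngs_ref / n_edge,
                n_edge=n_edge,
                n_ele=mesh.n_cells,
                order=order,
                n_dof=system.n_dofs,
                l2=l2_error(sol, case.exact),
                grad_probe=float(probe(sol, probe_point, 0, "gradient")[2]),
                wall_time=wall,
            ))
    return records


def records_to_csv(records, path) -> None:
    import pandas as pd
    pd.DataFrame([r.as_dict() for r in records]).to_csv(path, index=False)
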