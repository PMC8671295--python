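"""Column-length calibration and one-at-a-time sensitivity analysis.

Calibration: the equivalent grey/white column lengths (l_G, l_W) are the
two free parameters of the 1D tissue column; they are fitted so that the
column's whole/grey/white volume-averaged perfusion matches target values
taken from an organ-scale model.  The cost is the unweighted sum of
squared misfits in clinical units (all three targets share the same scale,
and with exact targets two parameters fit three dependent averages
exactly, since the whole-column average is the length-weighted mean of the
other two).

Sensitivity: each physiological parameter is perturbed one at a time over
[10%, 1000%] of its reference value; because the governing equations are
linear in pressure, one-at-a-time curves are representative of the global
behaviour.  Elasticities (percent output change per percent parameter
change) are read off the curve at the reference point by central
differences.  The 1D column is the fast engine; a 3D two-layer box with a
half-occluded pial face provides the organ-like cross-check including
infarct-volume fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.optimize import least_squares

from . import column1d, fem, postproc
from .column1d import column_averages, default_column_problem, solve_column
from .meshing import (BOTTOM, GREY, TOP, TOP_OCCLUDED, build_box_mesh)
from .params import ParameterSet, to_internal

__all__ = ["fit_column_lengths", "CalibrationResult", "SensitivityCurve",
           "oat_scan", "sensitivity_at_baseline", "default_scan_grid",
           "SCANNABLE_PARAMETERS", "CubeScenario", "scaled_parameters"]

SCANNABLE_PARAMETERS = ("cpp", "k1", "k2", "k3", "beta12_G", "beta23_G",
                        "beta_G_over_W", "geometry")


# -- calibration ---------------------------------------------------------------

@dataclass
class CalibrationResult:
    l_G: float
    l_W: float
    residual: float                       # root-sum-square misfit, ml/min/100ml
    achieved: np.ndarray                  # (total, grey, white) at the optimum


def fit_column_lengths(params: ParameterSet, targets,
                       bounds=((0.5, 0.5), (50.0, 50.0)),
                       x0=(10.0, 10.0), tol: float = 0.5) -> CalibrationResult:
    """Fit (l_G, l_W) in mm against perfusion targets (total, grey, white).

    Targets are in ml/min/100 ml.  A converged fit whose residual exceeds
    ``tol`` (same units) triggers a warning carrying the best point —
    e.g. for physically unreachable targets such as grey below white
    perfusion with a grey-dominant coupling ratio.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (3,) or np.any(targets <= 0):
        raise ValueError("need three positive perfusion targets (total, G, W)")
    internal = to_internal(params)

    def forward(L):
        av = column_averages(solve_column(default_column_problem(internal, *L)))
        return np.array([av.F_total, av.F_sub[0], av.F_sub[1]])

    res = least_squares(lambda L: forward(L) - targets, x0=np.asarray(x0),
                        bounds=(np.asarray(bounds[0]), np.asarray(bounds[1])),
                        xtol=1e-12, ftol=1e-14, gtol=1e-12)
    achieved = forward(res.x)
    misfit = float(np.linalg.norm(achieved - targets))
    if misfit > tol:
        warnings.warn(
            f"calibration residual {misfit:.3g} ml/min/100ml exceeds {tol}; "
            f"best point l_G={res.x[0]:.3f}, l_W={res.x[1]:.3f} achieves "
            f"{np.round(achieved, 2)} against {targets}", RuntimeWarning,
            stacklevel=2)
    return CalibrationResult(l_G=float(res.x[0]), l_W=float(res.x[1]),
                             residual=misfit, achieved=achieved)


# -- parameter perturbation ----------------------------------------------------

def scaled_parameters(base: ParameterSet, name: str, scale: float) -> ParameterSet:
    """Reference parameters with one entry multiplied by ``scale``.

    'k3' scales the venule/arteriole permeability ratio; 'geometry' is
    handled by the callers (it scales domain lengths, not a material
    parameter).
    """
    if name not in SCANNABLE_PARAMETERS:
        raise ValueError(f"unknown parameter {name!r}; "
                         f"choose from {SCANNABLE_PARAMETERS}")
    if name == "geometry":
        return base
    mapping = {"cpp": "cpp", "k1": "k1", "k2": "k2", "k3": "k3_over_k1",
               "beta12_G": "beta12_G", "beta23_G": "beta23_G",
               "beta_G_over_W": "beta_G_over_W"}
    attr = mapping[name]
    return replace(base, **{attr: getattr(base, attr) * scale})


def default_scan_grid(n: int = 101) -> np.ndarray:
    """Linear grid over [0.1, 10] x baseline with the baseline point kept."""
    grid = np.linspace(0.1, 10.0, n)
    if not np.any(np.isclose(grid, 1.0)):
        grid = np.sort(np.append(grid, 1.0))
    return grid


# -- scan engines --------------------------------------------------------------

def column_outputs(params: ParameterSet, l_G: float = 13.55,
                   l_W: float = 7.99) -> dict:
    """Healthy whole-column perfusion from the analytic 1D solver."""
    av = column_averages(solve_column(default_column_problem(params, l_G, l_W)))
    return {"F_healthy": av.F_total}


@dataclass
class CubeScenario:
    """Two-layer 3D box with a half-occluded pial face.

    The box spans the cortical-to-ventricular thickness (grey layer next to
    the TOP/pial face), with zero-flux lateral and bottom faces; occlusion
    removes the arteriole pressure condition from half of the pial surface
    (label TOP_OCCLUDED), mimicking a feeding-artery territory occlusion.
    """

    l_G: float = 13.55
    l_W: float = 7.99
    lateral: float = 10.0
    n: tuple = (3, 3, 7)
    order: int = 1

    def _mesh(self, geom_scale: float = 1.0):
        s = geom_scale ** (1.0 / 3.0)
        depth = (self.l_G + self.l_W) * s
        mesh = build_box_mesh(self.n, upper=(self.lateral * s, self.lateral * s,
                                             depth),
                              grey_above_z=self.l_W * s)
        # split the pial face: x below the midline is the occluded territory
        mid = 0.5 * self.lateral * s
        mesh = mesh.with_facet_relabel(
            lambda lab, c: TOP_OCCLUDED if lab == TOP and c[0] < mid else lab)
        return mesh

    def outputs(self, params: ParameterSet, geom_scale: float = 1.0) -> dict:
        from .orientation import anisotropic_K, solve_orientation
        internal = to_internal(params)
        mesh = self._mesh(geom_scale)
        # rank-1 arteriole/venule permeabilities along the descending
        # direction: without them lateral arteriole conductance would wash
        # out the occluded territory's perfusion deficit
        zeta = solve_orientation(mesh, [TOP, TOP_OCCLUDED], [BOTTOM])
        K = [anisotropic_K(zeta, internal.k[0]), internal.k[1],
             anisotropic_K(zeta, internal.k[2])]
        fields = fem.FieldSpec.from_params(internal, mesh, K_override=K)
        bcs = fem.BCSpec(dirichlet=[
            (0, TOP, internal.cpp_pa), (0, TOP_OCCLUDED, internal.cpp_pa),
            (2, TOP, 0.0), (2, TOP_OCCLUDED, 0.0)])
        healthy = fem.solve(fem.assemble(mesh, fields, bcs, self.order))
        occ_bcs = postproc.make_occlusion_bcs(bcs, TOP_OCCLUDED)
        occluded = fem.solve(fem.assemble(mesh, fields, occ_bcs, self.order))
        beta_cells = fields.beta_cells(mesh.n_cells)
        vol = mesh.cell_volumes()
        F_h = postproc.cell_perfusion(healthy, beta_cells)
        F_o = postproc.cell_perfusion(occluded, beta_cells)
        clin = 6000.0
        return {
            "F_healthy": float(np.sum(F_h * vol) / vol.sum() * clin),
            "F_occluded": float(np.sum(F_o * vol) / vol.sum() * clin),
            "infarct_fraction": postproc.infarct_fraction(F_h, F_o, vol),
        }


@dataclass
class SensitivityCurve:
    """One-at-a-time response of perfusion (and infarct) to one parameter."""

    parameter: str
    scales: np.ndarray
    F_healthy: np.ndarray
    F_occluded: Optional[np.ndarray] = None
    infarct_fraction: Optional[np.ndarray] = None
    failed_scales: list = field(default_factory=list)

    def output(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"curve carries no output {name!r}")
        return arr


def oat_scan(base: ParameterSet, parameter: str, scales=None,
             scenario: Optional[CubeScenario] = None,
             l_G: float = 13.55, l_W: float = 7.99) -> SensitivityCurve:
    """One-at-a-time scan of one parameter.

    Without a scenario the analytic 1D column supplies healthy perfusion;
    with a :class:`CubeScenario` the 3D box is re-solved at every scale and
    occluded perfusion plus infarct fraction are recorded too.  A solver
    failure at one scale is recorded and the scan continues.
    """
    if parameter not in SCANNABLE_PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; "
                         f"choose from {SCANNABLE_PARAMETERS}")
    scales = default_scan_grid() if scales is None else np.asarray(scales, float)
    rows, failed = [], []
    for s in scales:
        try:
            p = scaled_parameters(base, parameter, s)
            geom = s if parameter == "geometry" else 1.0
            if scenario is None:
                gs = geom ** (1.0 / 3.0)
                rows.append(column_outputs(p, l_G * gs, l_W * gs))
            else:
                rows.append(scenario.outputs(p, geom_scale=geom))
        except Exception:
            rows.append(None)
            failed.append(float(s))
    keys = next(r for r in rows if r is not None).keys()
    data = {k: np.array([r[k] if r is not None else np.nan for r in rows])
            for k in keys}
    return SensitivityCurve(parameter=parameter, scales=scales,
                            F_healthy=data["F_healthy"],
                            F_occluded=data.get("F_occluded"),
                            infarct_fraction=data.get("infarct_fraction"),
                            failed_scales=failed)


def sensitivity_at_baseline(curve: SensitivityCurve,
                            output: str = "F_healthy") -> float:
    """Normalised derivative (elasticity) at the reference point, scale 1.

    Central difference on the scan grid (the grid need not be uniform);
    a baseline on the grid edge falls back to a one-sided difference with
    a warning.
    """
    s = curve.scales
    y = curve.output(output)
    i = int(np.argmin(np.abs(s - 1.0)))
    if not np.isclose(s[i], 1.0):
        raise ValueError("scan grid does not contain the baseline scale 1.0")
    if i == 0 or i == len(s) - 1:
        warnings.warn("baseline on the grid edge; one-sided difference",
                      RuntimeWarning, stacklevel=2)
        j = i + 1 if i == 0 else i - 1
        dyds = (y[j] - y[i]) / (s[j] - s[i])
    else:
        dyds = (y[i + 1] - y[i - 1]) / (s[i + 1] - s[i - 1])
    y0 = y[i]
    if y0 == 0:
        return 0.0 if dyds == 0 else float("inf")
    return float(dyds * s[i] / y0)
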