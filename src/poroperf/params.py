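"""Physiological parameters and unit bookkeeping.

The perfusion model works internally in a mm–Pa–s unit system.  Published
permeabilities for the cerebral microcirculation are usually tabulated in
mm^3 s kg^-1; since 1 Pa = 1 kg mm^-1 s^-2 / 10^3 (with lengths in mm),
k [mm^3 s kg^-1] * 1e-3 = k [mm^2 Pa^-1 s^-1].  With that conversion the
arteriole penetration length sqrt(k1/beta12) is ~30 mm, commensurate with
the ~21.5 mm cortical-column thickness, which is what places the model in
the physiologically interesting regime rather than the well-mixed limit.

Compartments are indexed 1=arterioles, 2=capillaries, 3=venules.  The
inter-compartment coupling matrix beta is symmetric with zero diagonal;
by default there is no direct arteriole-venule shunt (beta13 = 0) because
pre-/post-capillary vessels are lumped into beta12 and beta23.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

# -- exact unit-conversion constants ----------------------------------------

#: 1 mmHg in Pa (fixed to six significant figures for reproducibility).
MMHG_TO_PA: float = 133.322

#: 1 s^-1 of volumetric exchange rate expressed in ml/min/100 ml of tissue.
#: (1 s^-1 = 60 s/min * 100 = 6000 ml/min/100 ml.)
PERFUSION_SI_TO_CLINICAL: float = 6000.0

#: mm^3 s kg^-1  ->  mm^2 Pa^-1 s^-1  (1 Pa = 10^3 kg mm^-1 s^-2 ... ^-1)
PERMEABILITY_TAB_TO_INTERNAL: float = 1.0e-3


class ParameterError(ValueError):
    """Raised for physically inadmissible parameter values."""


@dataclass
class ParameterSet:
    """Reference physiological constants of the three-compartment model.

    Permeabilities ``k1``, ``k2`` are in the tabulated mm^3 s kg^-1 units;
    ``k3`` is given through the dimensionless ratio ``k3_over_k1``.
    Coupling coefficients are grey-matter values in Pa^-1 s^-1; white-matter
    values follow by dividing by ``beta_G_over_W``.  ``cpp`` is the cerebral
    perfusion pressure in mmHg.
    """

    k1: float = 1.2344
    k2: float = 4.28e-4
    k3_over_k1: float = 2.0
    beta12_G: float = 1.326e-6
    beta23_G: float = 4.641e-6
    beta_G_over_W: float = 2.538
    cpp: float = 75.0
    beta13_G: float = 0.0
    n_compartments: int = 3

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.k3_over_k1 <= 0:
            raise ParameterError("permeabilities must be positive")
        if min(self.beta12_G, self.beta23_G, self.beta13_G) < 0:
            raise ParameterError("coupling coefficients must be non-negative")
        if self.beta_G_over_W <= 0:
            raise ParameterError("grey/white coupling ratio must be positive")
        if self.cpp <= 0:
            raise ParameterError("cerebral perfusion pressure must be positive")
        if self.n_compartments != 3:
            raise ParameterError("only the three-compartment model is supported")


@dataclass
class InternalParams:
    """Parameter bundle in the internal mm–Pa–s system.

    ``k`` holds the scalar permeabilities (mm^2 Pa^-1 s^-1) of the three
    compartments; ``beta_grey``/``beta_white`` are symmetric 3x3 coupling
    matrices (Pa^-1 s^-1) with zero diagonal; ``cpp_pa`` is in Pa.
    """

    k: np.ndarray
    beta_grey: np.ndarray
    beta_white: np.ndarray
    cpp_pa: float
    source: ParameterSet = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.k)

    def beta_for(self, tissue: str) -> np.ndarray:
        if tissue.upper() in ("G", "GREY", "GRAY"):
            return self.beta_grey
        if tissue.upper() in ("W", "WHITE",):
            return self.beta_white
        raise KeyError(f"unknown tissue label {tissue!r}")


def _symmetric_beta(b12: float, b23: float, b13: float) -> np.ndarray:
    beta = np.zeros((3, 3))
    beta[0, 1] = beta[1, 0] = b12
    beta[1, 2] = beta[2, 1] = b23
    beta[0, 2] = beta[2, 0] = b13
    return beta


def to_internal(params: ParameterSet) -> InternalParams:
    """Convert tabulated parameters to the internal mm–Pa–s system."""
    c = PERMEABILITY_TAB_TO_INTERNAL
    k = np.array([params.k1, params.k2, params.k1 * params.k3_over_k1]) * c
    beta_g = _symmetric_beta(params.beta12_G, params.beta23_G, params.beta13_G)
    beta_w = beta_g / params.beta_G_over_W
    return InternalParams(
        k=k,
        beta_grey=beta_g,
        beta_white=beta_w,
        cpp_pa=params.cpp * MMHG_TO_PA,
        source=params,
    )


def perfusion_to_clinical(f):
    """Volumetric exchange rate (s^-1) -> perfusion in ml/min/100 ml."""
    return np.asarray(f, dtype=float) * PERFUSION_SI_TO_CLINICAL


def clinical_to_perfusion(f):
    """Perfusion in ml/min/100 ml -> volumetric exchange rate (s^-1)."""
    return np.asarray(f, dtype=float) / PERFUSION_SI_TO_CLINICAL


def alpha_star(l_s: float, beta: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Dimensionless coupling group alpha*_ij = l_s^2 beta_ij / k_i.

    The row scaling by 1/k_i makes alpha* generally non-symmetric even for
    symmetric beta.  It controls the similarity of column solutions: two
    problems with equal alpha* have identical dimensionless pressure
    profiles.
    """
    beta = np.asarray(beta, dtype=float)
    k = np.asarray(k, dtype=float)
    if l_s <= 0:
        raise ParameterError("length scale must be positive")
    if np.any(k <= 0):
        raise ParameterError("permeabilities must be positive")
    return l_s**2 * beta / k[:, None]


# -- config I/O --------------------------------------------------------------

_CONFIG_KEYS = {
    "k1": "k1",
    "k2": "k2",
    "k3_over_k1": "k3_over_k1",
    "beta12_G": "beta12_G",
    "beta23_G": "beta23_G",
    "beta_G_over_W": "beta_G_over_W",
    "cpp_mmHg": "cpp",
    "beta13_G": "beta13_G",
}


def load_parameters(path) -> ParameterSet:
    """Read a ParameterSet from a YAML key-value file.

    Recognised keys: k1, k2, k3_over_k1, beta12_G, beta23_G, beta_G_over_W,
    cpp_mmHg (and optionally beta13_G).  Missing keys fall back to the
    reference values.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {path} must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _CONFIG_KEYS:
            raise ParameterError(f"unknown parameter key {key!r}")
        kwargs[_CONFIG_KEYS[key]] = float(value)
    return ParameterSet(**kwargs)


def save_parameters(params: ParameterSet, path) -> None:
    data = {
        "k1": params.k1,
        "k2": params.k2,
        "k3_over_k1": params.k3_over_k1,
        "beta12_G": params.beta12_G,
        "beta23_G": params.beta23_G,
        "beta_G_over_W": params.beta_G_over_W,
        "cpp_mmHg": params.cpp,
        "beta13_G": params.beta13_G,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
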