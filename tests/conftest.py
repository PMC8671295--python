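import numpy as np
import pytest

from poroperf import ParameterSet, to_internal
from poroperf.manufactured import load_default_case
from poroperf.meshing import build_unit_cube_mesh


@pytest.fixture(scope="session")
def reference_params():
    """Tabulated physiological reference values."""
    return ParameterSet()


@pytest.fixture(scope="session")
def internal_params(reference_params):
    return to_internal(reference_params)


@pytest.fixture(scope="session")
def ms_case():
    """Manufactured-solution verification case (bundled constants)."""
    return load_default_case()


@pytest.fixture(scope="session")
def cube4():
    return build_unit_cube_mesh(4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
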