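import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tbfe.materials import ElementMaterial
from tbfe.mesh import build_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(20230222)


@pytest.fixture
def column_mesh():
    """1x1x2 two-element column with 1 mm edges (uniaxial test bed)."""
    return build_mesh(np.ones((1, 1, 2), bool), 1000.0)


def uniform_material(ne, E=1000.0, S_max=10.0, S_sat=6.0, b=10.0):
    return ElementMaterial(
        E=np.full(ne, E), S_max=np.full(ne, S_max), S_sat=np.full(ne, S_sat),
        eps_el=np.full(ne, S_max / E), R1=np.full(ne, S_sat - S_max),
        b=np.full(ne, b))


def elastic_material(ne, E=1000.0):
    """Material that never yields within any test strain range."""
    big = 1e9
    return ElementMaterial(
        E=np.asarray(E, float) * np.ones(ne), S_max=np.full(ne, big),
        S_sat=np.full(ne, big), eps_el=np.full(ne, big) / (np.asarray(E, float) * np.ones(ne)),
        R1=np.zeros(ne))
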