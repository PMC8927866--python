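import logging

import numpy as np
import pytest

from scpot.contact_geometry import load_fixture_library
from scpot.synthetic import (
    CoupledWorldSpec, GeneratorSpec, generate_coupled_world, generate_synthetic_database,
)

# sparse-ensemble warnings are expected throughout desk-scale tests
logging.getLogger("scpot").setLevel(logging.ERROR)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.458   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1      -0.551   1.422   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       0.189   2.367   0.285  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def lib():
    return load_fixture_library()


@pytest.fixture(scope="session")
def small_db():
    """Ten small two-chain helix structures with mild dihedral noise."""
    return generate_synthetic_database(GeneratorSpec(n_structures=10, sigma=3.0), seed=11)


@pytest.fixture(scope="session")
def tiny_world():
    """A small geometry-coupled world for unit tests (not the acceptance scale)."""
    return generate_coupled_world(
        CoupledWorldSpec(n_structures=30, n_units=1, seg_len=5), seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
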