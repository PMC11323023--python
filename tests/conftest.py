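import numpy as np
import pytest

from coacervkit import parse_peptide
from coacervkit.droplet_electrostatics import ElectrolyteEnvironment


@pytest.fixture(scope="session")
def wr():
    return parse_peptide("WR")


@pytest.fixture(scope="session")
def w2r2():
    return parse_peptide("WWRR")


@pytest.fixture(scope="session")
def w3r3():
    return parse_peptide("WWWRRR")


@pytest.fixture(scope="session")
def study_env():
    """Electrolyte conditions of the droplet worked example."""
    return ElectrolyteEnvironment(relative_permittivity=78.4, debye_length_nm=2.42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
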