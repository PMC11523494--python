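import numpy as np
import pytest

from molartopo import (TopoConfig, make_fixture, make_molar, taubin_smooth,
                       cusped_molar_spec)


@pytest.fixture(scope="session")
def config():
    return TopoConfig()


@pytest.fixture(scope="session")
def flat_disc():
    return make_fixture("flat_disc", 32)


@pytest.fixture(scope="session")
def hemisphere():
    # ~13k faces: fine enough for the closed-form checks
    return make_fixture("hemisphere", 40)


@pytest.fixture(scope="session")
def single_cusp():
    return make_fixture("single_cusp", 64)


@pytest.fixture(scope="session")
def two_cusps():
    return make_fixture("two_cusps", 64)


@pytest.fixture(scope="session")
def molar_small():
    """A preprocessed cusped molar small enough for repeated full-metric
    computation (~3k faces)."""
    m = make_molar(cusped_molar_spec(seed=7, grid_n=40))
    return taubin_smooth(m, 0.9, -0.95, 10)


@pytest.fixture(scope="session")
def molar_tiny():
    """<2000 faces: the scale of the brute-force oracles."""
    m = make_molar(cusped_molar_spec(seed=11, grid_n=30))
    return taubin_smooth(m, 0.9, -0.95, 10)
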