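import numpy as np
import pytest

from gipet import reference


@pytest.fixture(scope="session")
def ga68():
    return reference.load_nuclide("ga68")


@pytest.fixture(scope="session")
def phantom_male():
    return reference.load_phantom("adult_male")


@pytest.fixture(scope="session")
def phantom_female():
    return reference.load_phantom("adult_female")


@pytest.fixture(scope="session")
def icrp60():
    return reference.load_tissue_weights("icrp60")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
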