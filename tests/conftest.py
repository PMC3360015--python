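import numpy as np
import pytest

from pdrehab import LesionSpec, Population, apply_lesion, unimanual


@pytest.fixture(scope="session")
def uniform500():
    return Population.uniform(500)


@pytest.fixture(scope="session")
def lesion():
    return LesionSpec()


@pytest.fixture(scope="session")
def lesioned500(uniform500, lesion):
    return apply_lesion(uniform500, lesion)


@pytest.fixture
def uni():
    return unimanual()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
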