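import numpy as np
import pytest
from hypothesis import settings

from amplimeth import ErrorModel, build_locus, convert_reference

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locus():
    """A 200 bp amplicon with 8 CpGs, 20 bp primer; fixed seed."""
    return build_locus("L1", 200, 8, gc_fraction=0.6, seed=7)


@pytest.fixture(scope="session")
def converted(locus):
    return convert_reference(locus)


@pytest.fixture(scope="session")
def error_free():
    return ErrorModel.error_free()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
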