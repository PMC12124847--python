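import numpy as np
import pytest
from hypothesis import settings

from rfspoil import TissueParams, build_default_protocol, zur_reference

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    """Default liquid-phantom protocol: TR 20 ms, TE 4 ms, 0.30 mm voxel."""
    return build_default_protocol()


@pytest.fixture(scope="session")
def zur():
    """Reference parameter set T1/TR = T2/TR = 20, D = 0."""
    return zur_reference(20.0)


@pytest.fixture(scope="session")
def h2o_cuso4():
    return TissueParams(t1=540.0, t2=340.0, d=1.93e-3)


@pytest.fixture(scope="session")
def silicone_oil():
    return TissueParams(t1=1290.0, t2=399.0, d=0.0055e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)
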