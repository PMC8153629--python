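import numpy as np
import pytest

from nemri.phantom import (
    AccumulationTruth,
    AcquisitionProtocol,
    ContrastAgentSpec,
    default_abdominal_phantom,
    default_aorta_phantom,
)


@pytest.fixture(scope="session")
def abdominal_phantom():
    return default_abdominal_phantom()


@pytest.fixture(scope="session")
def aorta_phantom():
    return default_aorta_phantom()


@pytest.fixture(scope="session")
def dynamic_protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def agent():
    return ContrastAgentSpec()


@pytest.fixture(scope="session")
def accumulation_truth():
    return AccumulationTruth(cmax_mM=2.0, tau_per_min=0.05)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
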