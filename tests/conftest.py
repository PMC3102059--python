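import numpy as np
import pytest

from klkbarrier.model import build_parameters


@pytest.fixture(scope="session")
def hc1():
    """HC condition, positive LEKTI feedback variant, nominal values."""
    return build_parameters("HC", 1, {})


@pytest.fixture(scope="session")
def hc1_nofeedback():
    return build_parameters("HC", 1, {"alphaK": 0.0, "alphaL": 0.0})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
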