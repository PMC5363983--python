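import numpy as np
import pytest

from nitocra.responses import default_responses


@pytest.fixture(scope="session")
def responses():
    return default_responses()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
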