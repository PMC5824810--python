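import numpy as np
import pytest

from memscaffold.energetics import MembraneMechanics


@pytest.fixture
def dopc() -> MembraneMechanics:
    """Default DOPC mechanics (kappa = 23.1 kBT, alpha = 3/pi, C0 = 0)."""
    return MembraneMechanics()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
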