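import numpy as np
import pytest

from wiafnet.config import ModelConfig
from wiafnet.synthetic_phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A deliberately small model for fast structural tests."""
    return ModelConfig.desk()


@pytest.fixture(scope="session")
def phantom32():
    """One 32-cube phantom case (volume, labelmap), session-cached."""
    return generate_phantom(PhantomSpec(grid=32), seed=7)
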