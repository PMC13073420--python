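import numpy as np
import pytest

from pancfat import AcquisitionParams, GeneratorConfig


@pytest.fixture
def params() -> AcquisitionParams:
    """Default 3 T dual-echo protocol."""
    return AcquisitionParams()


@pytest.fixture
def config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
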