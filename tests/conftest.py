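import numpy as np
import pytest

from berrylife.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    """The study-default generator configuration with a fixed master seed."""
    return SyntheticConfig(master_seed=20240111)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240111)
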