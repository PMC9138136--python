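import numpy as np
import pytest

from bioreact import CultureParams, RefreshProtocol, RunConfig


@pytest.fixture
def config() -> RunConfig:
    return RunConfig.default(n_wells=6, seed=1)


@pytest.fixture
def params() -> CultureParams:
    return CultureParams()


@pytest.fixture
def protocol() -> RefreshProtocol:
    """The published 48-h protocol: 6 wells, 2 mL refresh every 6 h, 8 cycles."""
    return RefreshProtocol.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
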