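import numpy as np
import pytest

from cagedrive import DriveParams, LifeHistoryParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_life():
    return LifeHistoryParams()


@pytest.fixture
def default_drive():
    return DriveParams()
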