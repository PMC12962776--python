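import numpy as np
import pytest

from ordtune import build_run_design
from ordtune.prf import HRFParams


@pytest.fixture(scope="session")
def default_design():
    return build_run_design()


@pytest.fixture(scope="session")
def canonical_hrf():
    return HRFParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
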