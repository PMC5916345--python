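import numpy as np
import pytest

from petkin.frames import make_frame_schedule
from petkin.synthetic import FengInput, simulate_reference_tac


@pytest.fixture(scope="session")
def ref_fmt():
    """Noiseless one-tissue reference TAC on the 25-frame/90-min schedule."""
    return simulate_reference_tac(FengInput(), 0.1, 0.1, make_frame_schedule("FMT"))


@pytest.fixture(scope="session")
def ref_rac():
    """Noiseless one-tissue reference TAC on the 19-frame/60-min schedule."""
    return simulate_reference_tac(FengInput(), 0.1, 0.1, make_frame_schedule("RAC"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
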