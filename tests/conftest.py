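import numpy as np
import pytest

import cectrack as ct
from cectrack.cec_core import DEFAULT_CHARGES, DEFAULT_CT_PARAMS


@pytest.fixture(scope="session")
def network_frame():
    return ct.make_ideal_network()


@pytest.fixture(scope="session")
def shuttle_series():
    return ct.make_shuttle_trajectory(n_waters_in_wire=4, hops=2, frames_per_hop=20)


@pytest.fixture
def params():
    return dict(DEFAULT_CT_PARAMS)


@pytest.fixture
def charges():
    return DEFAULT_CHARGES


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def jitter_frame(frame, rng, scale=0.02):
    """Small random displacement that preserves the bonding topology."""
    f = ct.Frame(
        list(frame.elements),
        frame.positions + rng.normal(scale=scale, size=frame.positions.shape),
        box=None if frame.box is None else frame.box.copy(),
        time=frame.time,
        index=frame.index,
    )
    return f
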