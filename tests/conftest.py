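import numpy as np
import pytest

from gasport.event_tracing import EventThresholds
from gasport.synthetic_gas import scripted_fixture


@pytest.fixture()
def thresholds():
    return EventThresholds(r_inner=6.0, r_outer=20.0, stride=10.0)


@pytest.fixture()
def dip_trajectory():
    """One molecule: 25 → 4 → 25 Å (one entry + one exit, hand-traceable)."""
    return scripted_fixture(
        [(0.0, "m", (25.0, 0, 0)), (30.0, "m", (4.0, 0, 0)), (60.0, "m", (25.0, 0, 0))],
        save_stride=10.0,
    )


@pytest.fixture()
def far_trajectory():
    """One molecule that never approaches the catalytic zone."""
    return scripted_fixture(
        [(0.0, "m", (30.0, 0, 0)), (50.0, "m", (32.0, 0, 0))], save_stride=10.0
    )
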