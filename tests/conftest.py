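import numpy as np
import pytest

from rosettemrf.sequence import build_schedule
from rosettemrf.trajectory import generate_rosette


@pytest.fixture(scope="session")
def paper_rosette():
    """The canonical 23-lobe readout (kmax 320 1/m, 18.4 ms, 2.5 us)."""
    return generate_rosette(320.0, 11.5, 7.5, 18.4, 2.5)


@pytest.fixture(scope="session")
def schedule_1000():
    """Default 15-heartbeat schedule at RR = 1000 ms."""
    return build_schedule([1000.0] * 15)


@pytest.fixture(scope="session")
def small_rosette():
    """Reduced readout for a 32-matrix grid (same lobe structure class)."""
    return generate_rosette(kmax=32 / 0.6, w1_cycles=5.5, w2_cycles=3.5,
                            readout_ms=8.0, dt_us=8.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
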