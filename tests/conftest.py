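import numpy as np
import pytest

from prexstim import SynthConfig
from prexstim.eeg_io import Recording
from prexstim.montage import CHANNELS_1020
from prexstim.synth import DIALECT_TRUSCAN


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(rng):
    """A 4 s, 19-channel recording of bounded white noise at 128 Hz."""
    samples = 50.0 * rng.standard_normal((19, 512))
    return Recording(
        channels=tuple(CHANNELS_1020), rate=128.0, samples=samples,
        reference="unknown",
    )


@pytest.fixture(scope="session")
def fast_cohort_config():
    """Truscan-dialect generator rendering at the native 128 Hz rate.

    All carriers live below 45 Hz, so rendering at 128 Hz is statistically
    identical to rendering at 1000 Hz and resampling; it keeps simulation
    tests fast.
    """
    return SynthConfig(dialect=DIALECT_TRUSCAN, source_rate=128.0)
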