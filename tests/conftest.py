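import numpy as np
import pytest

from swaquant import SimParams
from swaquant.core import Hypnogram


@pytest.fixture
def fast_params() -> SimParams:
    """Short, artifact-free simulation at an even rate for quick checks."""
    return SimParams(recording_hours=0.5, fs_native=200.0,
                     clipping_rate_per_h=0.0, spike_rate_per_h=0.0)


@pytest.fixture
def nrem_hypnogram() -> Hypnogram:
    """One hour scored entirely as NREM."""
    return Hypnogram(np.array(["NREM"] * 900))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
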