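import numpy as np
import pytest

from noisadapt.spectrogram import Spectrogram
from noisadapt.synth import TransitionSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_spec(rng):
    """Non-negative white stimulus spectrogram: 13 bands, 100 Hz, 60 s."""
    vals = rng.random((6000, 13))
    return Spectrogram(vals, 100.0, np.geomspace(180, 5400, 13))


def periodic_schedule(n_blocks=20, block_s=3.0, conds=("jet", "clean", "city", "bar")):
    """Deterministic no-repeat schedule for alignment tests."""
    onsets = np.arange(n_blocks) * block_s
    conditions = [conds[i % len(conds)] for i in range(n_blocks)]
    return TransitionSchedule(onsets, conditions, total_duration_s=n_blocks * block_s)


@pytest.fixture
def schedule20():
    return periodic_schedule()
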