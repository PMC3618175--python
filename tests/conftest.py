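import numpy as np
import pytest

from nightsong.audio_pipeline import SpectrogramParams, compute_spectrogram
from nightsong.synthetic_data import (
    build_catalogue,
    default_ll_grammar,
    default_lm_grammar,
)


@pytest.fixture(scope="session")
def lm_grammar():
    return default_lm_grammar()


@pytest.fixture(scope="session")
def ll_grammar():
    return default_ll_grammar()


@pytest.fixture(scope="session")
def params():
    return SpectrogramParams()


@pytest.fixture(scope="session")
def catalogue8():
    """Small reference catalogue shared across song-side tests."""
    return build_catalogue(8, seed=0)


@pytest.fixture(scope="session")
def tone_spec(params):
    sr = params.resample_rate
    t = np.arange(int(0.8 * sr)) / sr
    return compute_spectrogram(np.sin(2 * np.pi * 5000 * t), params, sr)
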