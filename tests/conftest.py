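import numpy as np
import pytest

from avmotion.cue_models import Modality
from avmotion.synthetic_data import (
    TABLE1_CONDITIONS,
    Condition,
    ObserverParams,
    canonical_gain_grid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gains():
    return canonical_gain_grid()


@pytest.fixture
def observer():
    """Biased, shared-noise observer with a fixed head speed."""
    return ObserverParams.from_gain_units(
        sigma_audio=0.10,
        sigma_visual=0.06,
        sigma_audio_jitter=0.18,
        sigma_visual_jitter=0.14,
        sigma_sm=0.05,
        head_mu=80.0,
        r_audio=0.97,
        r_visual=0.85,
    )


@pytest.fixture
def av_condition():
    return Condition(Modality.AUDIO_VISUAL)


@pytest.fixture
def all_conditions():
    return TABLE1_CONDITIONS
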