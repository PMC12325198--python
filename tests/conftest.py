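import numpy as np
import pytest

from vrgamma.montage import default_montage
from vrgamma.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_session(montage):
    """One reduced synthetic subject: 12 trials, 250 Hz, default gains."""
    cfg = SynthConfig(n_subjects=1, trials_per_group=3, fs=250.0, seed=42)
    return generate_session(cfg, 0, montage)


@pytest.fixture(scope="session")
def effect_session(montage):
    """One reduced subject with strong injected valence effects."""
    cfg = SynthConfig(n_subjects=1, trials_per_group=6, fs=250.0,
                      frontal_pos_gain=1.5, rt_neg_gain=1.5, seed=7)
    return generate_session(cfg, 0, montage)
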