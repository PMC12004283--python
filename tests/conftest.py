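import sys
from pathlib import Path

import numpy as np
import pytest

import hrvaffect as hv

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def default_protocol():
    return hv.generate_protocol(seed=1, n_stimuli=12)


@pytest.fixture
def regular_beats():
    """Perfectly regular 1000-ms beat series over two minutes."""
    return hv.BeatSeries(np.arange(0.0, 121.0, 1.0))


def constant_model(m0=1000.0, **delta):
    """Heart-period model with all modulation and noise off."""
    return hv.HeartPeriodModel(m0=m0, a_lf=0.0, a_hf=0.0, sigma=0.0,
                               delta=delta or {})


@pytest.fixture
def clean_subject(default_protocol):
    """Noise-free subject with a +40 ms acquaintance heart-period shift."""
    model = constant_model(m0=800.0, acquaintance=40.0, stranger=0.0)
    beats = hv.generate_beats(default_protocol, model, seed=1)
    return default_protocol, beats
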