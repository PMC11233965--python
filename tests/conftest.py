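import numpy as np
import pytest
from hypothesis import settings

import imprintlab as il

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def red_yellow():
    return il.red_yellow_continuum()


@pytest.fixture(scope="session")
def init_prefs(red_yellow):
    """Initial preference curve from the predisposition double-choice tests:
    Red1 and Orange equally preferred, Yellow1 about half as attractive."""
    choices = [
        il.PairwiseChoiceEstimate("Red1", "Orange", 0.5),
        il.PairwiseChoiceEstimate("Red1", "Yellow1", 2.0 / 3.0),
    ]
    return il.estimate_initial_prefs(choices, red_yellow, anchor="Red1")


@pytest.fixture(scope="session")
def receptors():
    return il.synthetic_uvs_receptors()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240607)
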