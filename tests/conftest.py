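import numpy as np
import pytest

from lambdaslider.alt_measures import load_svo_measure
from lambdaslider.slider_design import load_slider_fixtures


@pytest.fixture(scope="session")
def sliders():
    return load_slider_fixtures()


@pytest.fixture(scope="session")
def standard(sliders):
    """The reference quadratic slider: a=11.25, bs=70, bt=50, x in [-2, 2]."""
    return sliders["standard"]


@pytest.fixture(scope="session")
def svo_measure():
    return load_svo_measure()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
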