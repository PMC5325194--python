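import numpy as np
import pytest

from oxytitrate import default_distributions, paper_scenarios


@pytest.fixture
def dists():
    return default_distributions()


@pytest.fixture
def scenarios():
    return paper_scenarios()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
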