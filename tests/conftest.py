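import numpy as np
import pytest

from gaunet import SearchSpace


@pytest.fixture
def space():
    return SearchSpace()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_masks():
    """4x4 masks with tp=3, fp=1, fn=1, tn=11 by construction."""
    truth = np.zeros((4, 4), dtype=int)
    truth[0, 0] = truth[0, 1] = truth[1, 0] = truth[1, 1] = 1
    pred = np.zeros((4, 4), dtype=int)
    pred[0, 0] = pred[0, 1] = pred[1, 0] = pred[2, 2] = 1
    return pred, truth
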