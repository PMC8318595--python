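import numpy as np
import pytest

from tdlm.core import StateSpace
from tdlm.simulate import line_transition_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line4():
    """Forward matrix of the 4-state line A->B->C->D."""
    return line_transition_matrix(4)


@pytest.fixture
def random_space(rng):
    """Small white-noise decoded state space (200 x 4 at 100 Hz)."""
    return StateSpace(rng.standard_normal((200, 4)), 0.01)


def make_space(values, interval=0.01, **kw):
    return StateSpace(np.asarray(values, dtype=float), interval, **kw)
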