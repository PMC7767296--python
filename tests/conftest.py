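import numpy as np
import pytest

from sptclass import Trajectory2D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(positions, dt=1.0):
    return Trajectory2D(positions=np.asarray(positions, dtype=float), dt=dt)


@pytest.fixture
def straight_track():
    """Unit-speed ballistic path along +x with 10 steps."""
    return make_track([(i, 0.0) for i in range(11)])


@pytest.fixture
def random_track(rng):
    """A 60-step Brownian-like track for generic feature checks."""
    steps = rng.standard_normal((60, 2))
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return make_track(pos)
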