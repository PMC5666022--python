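import numpy as np
import pytest

from antdrip.lattice import Agent, World
from antdrip.params import SimParams


def make_world(inactive=(), active=(), rod=(500, 500), threshold=5.0):
    """Build a world with inactive agents at the given sites (one each) and
    active agents at the given sites (stacking allowed)."""
    w = World(rod=rod)
    for site in inactive:
        a = w.new_agent(*site)
        w.active.remove(a)
        a.active = False
        a.threshold = threshold
        w.inactive[site] = a
    for site in active:
        w.new_agent(*site)
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return SimParams(seed=1)
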