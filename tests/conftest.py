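import numpy as np
import pytest

import oscpattern as op


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line3():
    """Line of 3 oscillators with increasing frequencies [-1, 0, 1]."""
    return op.make_topology("line", 3).with_omega([-1.0, 0.0, 1.0])


@pytest.fixture
def triangle():
    """Homogeneous triangle: unit weights, zero frequencies."""
    return op.make_topology("complete", 3)


def random_connected_network(rng, n, weight_low=0.5, weight_high=2.0):
    """Random connected topology with random positive weights, zero omega."""
    seed = int(rng.integers(0, 2**31 - 1))
    skel = op.make_topology("random_connected", n, seed=seed)
    return skel.with_delta(rng.uniform(weight_low, weight_high, skel.m))
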