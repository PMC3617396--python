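import numpy as np
import pytest

from dynsyn.attractor_network import PatternSet
from dynsyn.tm_synapse import TMParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_neuron_pattern():
    """The hand-calculated single-pattern set xi = (1, 1, 0, 0), a = 1/2."""
    return PatternSet(xi=np.array([[1, 1, 0, 0]], dtype=np.int8), a=0.5)


@pytest.fixture
def depressing():
    return TMParams(U=1.0, tau_rec=26.0, tau_fac=1.0, mode="depression_only")


@pytest.fixture
def static():
    return TMParams(U=1.0, tau_rec=1.0, tau_fac=1.0, mode="static")
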