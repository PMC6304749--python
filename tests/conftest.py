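import numpy as np
import pytest

from devsnn.connectivity import LatticeGeometry
from devsnn.model_core import MaturationState, NeuronParams, SynapseParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neuron_params():
    return NeuronParams()


@pytest.fixture
def synapse_params():
    return SynapseParams()


@pytest.fixture
def immature():
    return MaturationState.immature()


@pytest.fixture
def mature():
    return MaturationState.mature()


@pytest.fixture
def unit_geometry(rng):
    """200 neurons uniformly placed on the unit lattice."""
    return LatticeGeometry.uniform_random(200, rng)
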