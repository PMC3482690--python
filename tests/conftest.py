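import numpy as np
import pytest

from plumebrain.brain import NetworkConfig, build_network, permissive_params
from plumebrain.fluid import FlowGrid


@pytest.fixture
def small_grid() -> FlowGrid:
    """16x16 oracle grid with exact-projection test settings."""
    return FlowGrid(nx=16, ny=16, cell_size=0.05, solver_iters=200)


@pytest.fixture
def tiny_config() -> NetworkConfig:
    """Minimal circuit for hand-checkable dynamics: one unit per layer."""
    return NetworkConfig(
        n_sensors=4,
        sensors_per_mitral=4,
        n_inter=1,
        inter_fanin=1,
        n_cortex=1,
        branches=1,
        exc_per_branch=1,
        inh_per_branch=1,
        n_motor=1,
        motor_fanin=1,
    )


@pytest.fixture
def permissive_tiny_net(tiny_config):
    # inhibition scaled down so the single-synapse branch stays net excitatory
    from plumebrain.brain import SynapseClassParams

    params = permissive_params()
    classes = dict(params.classes)
    classes["inter_cortex"] = SynapseClassParams(weight=-0.25)
    from dataclasses import replace

    return build_network(replace(params, classes=classes), tiny_config, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
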