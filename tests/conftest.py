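import numpy as np
import pytest

import rowgraph as rg


@pytest.fixture(scope="session")
def small_gem():
    """A small random-init GEM: (params, config)."""
    config = rg.ModelConfig(mode="2D", model_type="GEM", node_state_dim=8,
                            graph_vector_dim=8, rounds=3, seed=7)
    return rg.init_params(config), config


@pytest.fixture(scope="session")
def small_gmn():
    config = rg.ModelConfig(mode="2D", model_type="GMN", node_state_dim=8,
                            graph_vector_dim=8, rounds=3, seed=7)
    return rg.init_params(config), config


@pytest.fixture(scope="session")
def short_seq():
    """Noise-free 2-stroke sequence, period 60."""
    spec = rg.RowerSpec(profile=rg.StrokeProfile(period=60), seed=3)
    return rg.simulate(spec, n_frames=120)


@pytest.fixture(scope="session")
def noisy_seq():
    spec = rg.RowerSpec(profile=rg.StrokeProfile(period=60),
                        noise_sigma=2.0, seed=5)
    return rg.simulate(spec, n_frames=120)
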