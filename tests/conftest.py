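import numpy as np
import pytest

from spikefrr import (ModelSpec, NoiseSpec, SimConfig, SpikeShape,
                      simulate_if)

# model/noise scales used throughout: threshold 1, reset 0, leaky drift
# mu - v with subthreshold mu = 0.8, white noise intensity 0.1


@pytest.fixture(scope="session")
def white_run():
    """Moderate spontaneous white-noise run shared by several tests."""
    shape = SpikeShape.clamp(0.1)
    model = ModelSpec(mu=0.8, shape=shape)
    noise = NoiseSpec.white(0.1)
    cfg = SimConfig(dt=1e-3, window_steps=2**13, n_windows=128, seed=1234)
    return simulate_if(model, noise, None, cfg)


@pytest.fixture(scope="session")
def deterministic_run():
    """Suprathreshold noise-free run: perfectly periodic firing."""
    shape = SpikeShape.clamp(0.1)
    model = ModelSpec(mu=1.5, shape=shape)
    noise = NoiseSpec.white(1e-12)
    cfg = SimConfig(dt=1e-4, window_steps=2**13, n_windows=32, seed=7)
    return simulate_if(model, noise, None, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
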