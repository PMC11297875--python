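import numpy as np
import pytest

from spikemode import (DatasetSpec, DecayInitScheme, TrainConfig, make_dataset,
                       train)
from spikemode.encoding import SpikeTrainBatch
from spikemode.lif_network import LIFParams, simulate_layer


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """4-class, 8x8, 240 samples — enough for fast train/eval smoke paths."""
    spec = DatasetSpec(n_samples=240, image_side=8, n_classes=4,
                       target_mean_brightness=40, noise_sd=6, seed=5)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def tiny_binned_model(tiny_dataset):
    """A quickly trained binned-uniform model (16 neurons, 4 bins)."""
    config = TrainConfig(hidden_size=16, n_steps=40, epochs=3, batch_size=64,
                         seed=0)
    scheme = DecayInitScheme(mode="binned_uniform", n_bins=4, neurons_per_bin=4)
    return train(tiny_dataset, config, scheme)


@pytest.fixture(scope="session")
def random_simulation():
    """Random positive-and-negative-weight layer on Poisson input, with the
    full membrane trace — shared substrate for attribution tests."""
    gen = np.random.default_rng(42)
    n_channels, n_neurons, n_steps = 12, 8, 40
    w = gen.normal(0.0, 0.35, size=(n_channels, n_neurons))
    t_decay = np.linspace(15.0, 480.0, n_neurons)
    params = LIFParams(w_input=w, t_decay=t_decay, n_steps=n_steps)
    spikes = SpikeTrainBatch(
        (gen.random((20, n_steps, n_channels)) < 0.25).astype(np.uint8))
    trace = simulate_layer(spikes, params)
    return spikes, trace, params
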