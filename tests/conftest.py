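import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make naive_ref importable

from fatiguenet import Epoch, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """4-channel config for fast spectral checks (Pz/O1 affected)."""
    return SimulationConfig(
        n_channels=4,
        channel_names=["Fz", "Cz", "Pz", "O1"],
        duration=10.0,
        seed=11,
    )


@pytest.fixture
def random_epoch(rng):
    """A default-geometry 32 x 2000 epoch of white noise at 200 Hz."""
    return Epoch(data=rng.standard_normal((32, 2000)), rate=200.0)


def make_tiny_epochs(rng, n_per_class=6, n_channels=32, n_samples=256,
                     rate=200.0, shift=1.5):
    """Small labelled epochs with a class-dependent mean pattern on a
    few channels — separable without any heavy simulation."""
    epochs, labels = [], []
    pattern = np.zeros((n_channels, 1))
    pattern[-6:] = shift
    for label, offset in (("awake", 0.0), ("fatigue", 1.0)):
        for _ in range(n_per_class):
            base = rng.standard_normal((n_channels, n_samples))
            data = base + offset * pattern * np.sin(
                2 * np.pi * 10 * np.arange(n_samples) / rate
            )
            epochs.append(Epoch(data=data, rate=rate, label=label))
            labels.append(label)
    return epochs, labels


@pytest.fixture
def tiny_labelled_epochs(rng):
    return make_tiny_epochs(rng)
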