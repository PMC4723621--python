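import numpy as np
import pytest

from metabofuse.synthdata import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small two-class design for fast end-to-end exercises."""
    return SimulationConfig(
        n_samples_per_class=6,
        n_classes=2,
        platform_dims={"alpha": 8, "beta": 5},
        n_discriminative={"alpha": 2, "beta": 1},
        effect_size=2.0,
        noise_sd=0.3,
        seed=42,
    )


@pytest.fixture
def separable_xy(rng):
    """Strongly separated two-class matrix for classification checks."""
    n_per, p = 10, 30
    X = rng.normal(0.0, 1.0, (2 * n_per, p))
    X[:n_per, :10] += 4.0
    labels = ["a"] * n_per + ["b"] * n_per
    return X, labels
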