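import numpy as np
import pytest

from spectrafuse import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fully deterministic dataset configuration."""
    return SyntheticConfig(
        n_per_class=(10, 10, 10, 10, 10),
        class_effect_scale=1.0,
        noise_sd=0.01,
        complementarity=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_records(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def tiny_cnn_overrides():
    """CNN-S config overrides small enough for fast structural tests."""
    return dict(conv_channels=(2, 3, 3), dense_sizes=(16, 8, 5), attention_hidden=4)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
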