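import numpy as np
import pytest

from fpnseg import (
    ModelConfig,
    PhantomConfig,
    generate_phantom,
    preprocess_records,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom_config():
    return PhantomConfig(image_size=(64, 64), tumor_probability=1.0, seed=99)


@pytest.fixture
def positive_record(phantom_config):
    """One preprocessed 64x64 phantom guaranteed to contain a tumor."""
    rec = generate_phantom(phantom_config, np.random.default_rng(99), force_tumor=True)
    return preprocess_records([rec])[0]


@pytest.fixture
def tiny_model_config():
    """Model small enough for fast unit tests (not the experiment preset)."""
    return ModelConfig(
        input_size=(32, 32, 3), encoder_widths=(4, 8, 12, 16, 24), lateral_channels=8, seed=0
    )


def random_binary_pair(rng, shape=(16, 16), p=0.3):
    pred = (rng.random(shape) < p).astype(np.uint8)
    ref = (rng.random(shape) < p).astype(np.uint8)
    return pred, ref
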