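import numpy as np
import pytest

from bayesenc import (ConvEncoder, EncoderConfig, ScaleMixturePrior,
                      make_dataset)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small LNP dataset for fast training tests (8 neurons, 12x12)."""
    ds, pop = make_dataset(n_neurons=8, hw=(12, 12), n_train=400, n_val=100,
                           n_test=25, n_repeats=6, seed=11)
    return ds, pop


@pytest.fixture
def tiny_config():
    return EncoderConfig(in_channels=1, input_hw=(12, 12), n_neurons=8,
                         conv1=(6, 5, 5), conv2=(6, 3, 3),
                         variant="variational")


@pytest.fixture
def micro_variational():
    """~100-parameter variational encoder for exact/gradient tests."""
    cfg = EncoderConfig(in_channels=1, input_hw=(5, 5), n_neurons=2,
                        conv1=(2, 3, 3), conv2=(2, 2, 2),
                        variant="variational")
    return ConvEncoder(cfg, prior=ScaleMixturePrior(), seed=3)


@pytest.fixture
def micro_batch():
    rng = np.random.default_rng(42)
    stim = rng.standard_normal((4, 1, 5, 5))
    resp = rng.poisson(1.0, (4, 2)).astype(float)
    return stim, resp
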