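import numpy as np
import pytest

from structssl.pipeline import ModelConfig, TrainConfig, init_model, prepare_proteins
from structssl.synth import make_ideal_helix, make_random_coil, make_toy_dataset


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    """Small architecture used throughout: keeps forward passes cheap."""
    return ModelConfig(hidden_dim=16, emb_dim=8, rbf_centers=8)


@pytest.fixture(scope="session")
def tiny_train_cfg() -> TrainConfig:
    return TrainConfig(epochs_pretrain=2, batch_size=4, seed=0)


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12, seed=0)


@pytest.fixture(scope="session")
def coil20():
    return make_random_coil(20, seed=1)


@pytest.fixture(scope="session")
def toy_batch(tiny_cfg):
    """Four prepared proteins (mixture) plus freshly seeded parameters."""
    ds = make_toy_dataset(4, (8, 12), 3, seed=7)
    prepared = prepare_proteins(ds.structures, tiny_cfg)
    params = init_model(tiny_cfg, seed=1)
    return prepared, params


@pytest.fixture
def rng():
    return np.random.default_rng(0)
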