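import numpy as np
import pytest

from admvnet.model import ModelConfig
from admvnet.gpm import GPMConfig
from admvnet.mlca import MLCAConfig
from admvnet.pipeline import TrainConfig, VolumeDataset
from admvnet.synthetic import SyntheticConfig, generate_dataset, make_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_parcellation():
    return make_parcellation((16, 16, 16), seed=1)


def tiny_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """Smallest usable network (c4 = 8) for wiring/speed-sensitive tests."""
    kwargs = dict(widths=(4, 8, 8, 8),
                  gpm=GPMConfig(n_heads=2),
                  mlca=MLCAConfig(aligned_channels=8),
                  seed=seed)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def tiny_train_config(seed: int = 0, **overrides) -> TrainConfig:
    kwargs = dict(lr=0.01, batch_size=4, epochs=2, folds=2, seed=seed)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 subjects with 16^3 volumes and a strong planted effect."""
    cfg = SyntheticConfig(n_per_class=8, shape=(16, 16, 16),
                          gm_effect=2.0, wm_effect=2.0, pet_effect=3.0, seed=7)
    samples, parc = generate_dataset(cfg)
    return VolumeDataset(samples, parc)
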