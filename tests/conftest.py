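import numpy as np
import pytest

from milpath.config import CohortSpec, ModelConfig, TrainConfig
from milpath.synthetic import generate_feature_bags


def small_cohort(separation: float, seed: int = 0, dim: int = 64):
    """A reduced cohort (24 slides, 64-d bags) for fast training tests."""
    spec = CohortSpec(n_good=10, n_medium=8, n_bad=6, n_train=16, n_val=8,
                      n_external=4, separation=separation, domain_shift=0.5,
                      seed=seed)
    samples = generate_feature_bags(spec, bag_size_range=(8, 16), dim=dim)
    train = [b for b, _, _, s in samples if s == "train"]
    val = [b for b, _, _, s in samples if s == "val"]
    ext = [b for b, _, _, s in samples if s == "external"]
    return train, val, ext


def tiny_model_cfg() -> ModelConfig:
    return ModelConfig(embed_dim=32, n_heads=4, n_layers=1, scales=(2, 4))


def tiny_train_cfg(**overrides) -> TrainConfig:
    params = dict(batch_size=8, max_epochs=6, n_members=2)
    params.update(overrides)
    params.setdefault("patience", params["max_epochs"] - 1)
    return TrainConfig(**params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sep6_small():
    return small_cohort(6.0, seed=0)


@pytest.fixture(scope="session")
def sep0_small():
    return small_cohort(0.0, seed=0)
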