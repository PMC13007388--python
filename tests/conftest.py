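import numpy as np
import pytest

from fiberparc import (
    ModelConfig,
    StreamlineTransformer,
    TrainConfig,
    bilateral6_spec,
    make_phantom,
    train_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """~1000-streamline bilateral phantom (6 classes + outlier) shared by tests."""
    return make_phantom(bilateral6_spec(n_per_bundle=150, seed=0))


@pytest.fixture(scope="session")
def desk_model_cfg():
    return ModelConfig(d_model=64, n_layers=2, ffn_hidden=128, clf_hidden=128,
                       n_classes=7, n_points=15)


@pytest.fixture(scope="session")
def tiny_trained(small_phantom):
    """A quickly trained model for inference-path tests (not for accuracy claims)."""
    t, lm = small_phantom
    cfg = ModelConfig(d_model=64, n_layers=1, ffn_hidden=64, clf_hidden=64,
                      n_classes=7, n_points=15)
    tcfg = TrainConfig(batch_size=1, epochs=200, context_size=128, seed=0,
                       val_every=100, n_val_subtractograms=2)
    model, history = train_model([t], cfg, tcfg)
    return model, history, t, lm
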