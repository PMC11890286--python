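import numpy as np
import pytest

import ncfuse as nf


@pytest.fixture(scope="session")
def tiny_dataset():
    """90 samples, 3 classes, all modalities, default signal strengths."""
    return nf.simulate_dataset(nf.SynthConfig(n_per_class=30, seed=101))


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained compact model on the tiny dataset."""
    cfg = nf.ModelConfig.from_dataset(tiny_dataset)
    model, _ = nf.train(tiny_dataset, cfg, nf.desk_train_config(seed=3, epochs=4))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
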