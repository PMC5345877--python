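import numpy as np
import pytest

from motifgate.synthetic import make_world


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """Cheap shared world for non-training tests."""
    return make_world(6, 4, 6, 0.7, rng=np.random.default_rng(7), seed=7)


@pytest.fixture(scope="session")
def downstream_model():
    """A model trained on every combination of a synthetic world via the
    merge-then-retrain protocol; shared by training/downstream/acceptance
    tests (takes ~1-2 minutes once per session)."""
    from motifgate.experiments import train_downstream_model
    return train_downstream_model(seed=5)
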