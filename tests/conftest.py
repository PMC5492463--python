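import numpy as np
import pytest

from semg_actmon.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One-subject dataset, 6 epochs per activity, default signal model."""
    cfg = GeneratorConfig(seed=11, n_epochs_per_class=6, n_subjects=1)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def cv_dataset():
    """One-subject dataset large enough for five-fold evaluation."""
    cfg = GeneratorConfig(seed=23, n_epochs_per_class=10, n_subjects=1)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
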