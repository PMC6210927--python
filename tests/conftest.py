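import numpy as np
import pytest

import tugsense as ts


@pytest.fixture(scope="session")
def train_corpus():
    """Small labeled corpus for fitting models in unit tests."""
    return ts.generate_corpus(20, seed=11)


@pytest.fixture(scope="session")
def trained_model(train_corpus):
    """Hierarchy trained on the small corpus with the default configuration."""
    return ts.train_hierarchy(train_corpus.recordings, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
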