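import numpy as np
import pytest

from spineimu.features import WindowSpec, build_dataset
from spineimu.selection import rank_features
from spineimu.synthetic import synthesize_location_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def location_corpus():
    """Full 12-subject placement corpus (all 10 exercises x 5 sites)."""
    return synthesize_location_dataset(n_subjects=12, seed=7)


@pytest.fixture(scope="session")
def corpus_features(location_corpus):
    """Windowed features of the corpus at stride 50 (scaled-down stride)."""
    return build_dataset(location_corpus, WindowSpec(stride_samples=50))


@pytest.fixture(scope="session")
def corpus_ranking(corpus_features):
    return rank_features(corpus_features, seed=7)
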