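import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tcelsig.io import ExpressionMatrix, GeneSignature
from tcelsig.simulate import CorpusSpec, generate_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus():
    """Default planted corpus, fixed seed."""
    return generate_corpus(CorpusSpec(), seed=0)


@pytest.fixture(scope="session")
def all_candidates(corpus):
    return GeneSignature("candidates", list(corpus.matrix.gene_ids))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, hand-enterable values."""
    values = pd.DataFrame(
        [[8.0, 7.5, 4.0, 3.0], [10.0, 9.0, 5.0, 6.0], [2.0, 2.5, 2.0, 1.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)
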