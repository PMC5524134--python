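import numpy as np
import pytest

from mhcmotif import (
    ScoringMatrix,
    default_planted_model,
    generate_dataset,
)


@pytest.fixture
def zero_matrix():
    return ScoringMatrix(allele="TEST", values=np.zeros((20, 9)), intercept=3.0)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    return ScoringMatrix(
        allele="TEST", values=rng.normal(0, 1, size=(20, 9)), intercept=2.0
    )


@pytest.fixture(scope="session")
def planted_model():
    """Standard benchmark model: 9-mer, P2/P9 anchors, sigma=0.1, n=2000."""
    return default_planted_model(seed=7)


@pytest.fixture(scope="session")
def planted_dataset(planted_model):
    return generate_dataset(planted_model)


@pytest.fixture
def small_dataset():
    model = default_planted_model(seed=11, n_peptides=300)
    return generate_dataset(model)
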