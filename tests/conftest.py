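import numpy as np
import pytest

from tdfuse.io_formats import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 50-gene x 5-sample study with arbitrary values."""
    return ExpressionMatrix(
        gene_ids=[f"G{i:03d}" for i in range(50)],
        sample_ids=[f"S{j}" for j in range(5)],
        values=rng.normal(size=(50, 5)),
    )


@pytest.fixture
def normalized_matrix(small_matrix):
    from tdfuse.preprocess import normalize_per_sample

    return normalize_per_sample(small_matrix)
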