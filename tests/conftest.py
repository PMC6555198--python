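import numpy as np
import pytest

from transtat.io_formats import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_ids=None, sample_ids=None, is_raw_counts=None):
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_g)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_s)]
    if is_raw_counts is None:
        is_raw_counts = bool(np.all(values == np.floor(values)))
    return ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, is_raw_counts=is_raw_counts
    )


@pytest.fixture
def small_matrix():
    return make_matrix(
        [[10, 20, 30], [5, 5, 5], [0, 1, 100], [7, 70, 700]],
        gene_ids=["a", "b", "c", "d"],
        sample_ids=["s1", "s2", "s3"],
    )


@pytest.fixture
def random_counts(rng):
    return make_matrix(rng.integers(0, 500, size=(50, 6)).astype(float))
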