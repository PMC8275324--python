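import numpy as np
import pytest

from scdoublet import ErrorModel, LocusPriors, ReadCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_priors():
    def make(m=1, ids=None):
        ids = ids if ids is not None else [f"L{j:03d}" for j in range(m)]
        return LocusPriors.global_triple([1 / 3, 1 / 3, 1 / 3], ids)

    return make


@pytest.fixture
def default_err():
    return ErrorModel(beta=0.05, alpha_fp=0.001, alpha_fn=0.001, s=15.0, delta=0.2)


@pytest.fixture
def small_counts(rng):
    """A tiny labelled count matrix with assorted depths including zeros."""
    total = np.array([[50, 0, 30], [10, 40, 25], [60, 55, 0]])
    alt = np.array([[25, 0, 1], [0, 39, 7], [30, 2, 0]])
    return ReadCounts(
        droplet_ids=np.array(["d0", "d1", "d2"], dtype=object),
        locus_ids=np.array(["L0", "L1", "L2"], dtype=object),
        total=total,
        alt=alt,
    )
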