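import logging

import numpy as np
import pytest

import capssa as cs

# Clamp warnings from tiny-text sampling are expected noise in tests.
logging.getLogger("capssa.partition").setLevel(logging.ERROR)

#: The example text used throughout: T = AACTGCGGAT with terminator.
EXAMPLE_SA = [10, 0, 1, 8, 5, 2, 7, 4, 6, 9, 3]
EXAMPLE_LCP = [0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1]


@pytest.fixture(scope="session")
def example_text():
    return cs.build_text("AACTGCGGAT")


@pytest.fixture(scope="session")
def example_sa():
    return np.asarray(EXAMPLE_SA, dtype=np.int64)


@pytest.fixture(scope="session")
def example_lcp():
    return np.asarray(EXAMPLE_LCP, dtype=np.int64)


def random_text(n, alphabet_size=4, seed=0):
    rng = np.random.default_rng(seed)
    body = rng.integers(65, 65 + alphabet_size, size=n).astype(np.uint8)
    return cs.build_text(body)
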