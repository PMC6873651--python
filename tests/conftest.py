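import numpy as np
import pytest

from sweepnet import HaplotypeAlignment, generate_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_alignment():
    """4 haplotypes x 3 segregating sites, hand-written."""
    return HaplotypeAlignment(
        np.array([[0, 1, 1], [1, 0, 1], [0, 1, 0], [0, 0, 1]]),
        np.array([0.1, 0.5, 0.9]),
    )


@pytest.fixture
def random_alignments():
    """20 neutral fixtures of mixed shapes for round-trip style tests."""
    out = []
    for seed in range(10):
        out += generate_fixtures(2, 8 + 2 * seed, 5 + seed, rng_seed=seed)
    return out
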