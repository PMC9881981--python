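import numpy as np
import pytest

from hqalign import compute_thresholds, synthesize_qmer_map


@pytest.fixture(scope="session")
def qmap6():
    return synthesize_qmer_map(6, seed=11)


@pytest.fixture(scope="session")
def cfg6(qmap6):
    return compute_thresholds(qmap6, 3)


@pytest.fixture(scope="session")
def qmap2():
    return synthesize_qmer_map(2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
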