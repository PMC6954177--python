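import numpy as np
import pytest

from clonekin.repertoire import RepertoireSample


@pytest.fixture
def small_sample() -> RepertoireSample:
    return RepertoireSample({"A": 40, "B": 30, "C": 20, "D": 10})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_repertoire(rng: np.random.Generator, n: int = 20, max_count: int = 200):
    """A random small repertoire with positive integer counts."""
    counts = rng.integers(1, max_count, size=n)
    return RepertoireSample({f"CT{i:03d}": int(c) for i, c in enumerate(counts)})
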