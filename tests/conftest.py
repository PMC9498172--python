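import numpy as np
import pytest

from mixedcmi import MixedSample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_mixed_sample(rng, n=40, n_quant=2, n_qual=2, n_categories=3):
    """A generic mixed sample for property tests."""
    cols = [rng.normal(size=n) for _ in range(n_quant)]
    cols += [rng.integers(0, n_categories, size=n).astype(float) for _ in range(n_qual)]
    qual = [False] * n_quant + [True] * n_qual
    return MixedSample(np.column_stack(cols), np.array(qual))
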