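import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20140704)


@pytest.fixture
def random_counts(rng):
    """A batch of random multinomial count vectors from assorted trees."""
    from longbranch.patterns import pattern_class_probs_3

    out = []
    for d in [(0.1, 0.1, 0.1), (0.1, 0.1, 1.0), (0.3, 0.2, 2.0), (0.05, 0.4, 0.8)]:
        p = pattern_class_probs_3(d)
        out.append(rng.multinomial(300, p, size=5))
    return np.vstack(out)
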