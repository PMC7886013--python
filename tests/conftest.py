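import numpy as np
import pytest

from scanclust import AOIRegion, AOIScheme, AOISequence


@pytest.fixture
def mastermind_scheme() -> AOIScheme:
    """Six stacked AOIs: five conjecture rows on the left, response on the right."""
    rows = [AOIRegion(i, 0, (i - 1) * 100, 400, i * 100) for i in range(1, 6)]
    response = AOIRegion(6, 400, 0, 700, 500)
    return AOIScheme(d=6, regions=tuple(rows + [response]))


@pytest.fixture
def seq_factory():
    def make(labels, d=6, participant="p1", item="i1", true_strategy=None):
        return AOISequence(
            participant=participant,
            item=item,
            labels=list(labels),
            d=d,
            true_strategy=true_strategy,
        )

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
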