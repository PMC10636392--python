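import numpy as np
import pytest

from fgba import Landscape, Params


@pytest.fixture
def table1() -> Params:
    """The standard rate set (phi left at 0; set per test)."""
    return Params()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_landscape(rng, width=12, height=12, p=(0.4, 0.4, 0.1, 0.1)):
    """Random four-state landscape for property tests."""
    cells = rng.choice(4, size=(height, width), p=p).astype(np.uint8)
    return Landscape(cells)
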