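import numpy as np
import pytest

from flyspace.arena import ArenaGeometry, equilateral_arena


@pytest.fixture
def arena() -> ArenaGeometry:
    """Default equilateral chamber: 80 mm side, 2 mm wall margin."""
    return equilateral_arena(side=80.0, margin=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
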