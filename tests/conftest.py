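import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from oracles import random_protein  # noqa: E402


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230517)


@pytest.fixture
def random_sequences(rng):
    """100 random sequences of varied length for property checks."""
    return [random_protein(rng, int(rng.integers(10, 200))) for _ in range(100)]
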