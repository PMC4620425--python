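import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from rocboost import COARSE_GRID, enumerate_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def coarse_specs():
    return enumerate_grid(COARSE_GRID)


@pytest.fixture
def random_image(rng):
    return rng.integers(0, 256, size=(120, 100, 3), dtype=np.uint8)
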