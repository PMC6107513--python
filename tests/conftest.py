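import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from sekit.simulate import LandscapeConfig, generate

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_landscape():
    """The standard synthetic fixture (seed 1): 20 SEs vs 400 TEs."""
    return generate(LandscapeConfig())


@pytest.fixture(scope="session")
def erna_toy_dir() -> Path:
    return DATA_DIR / "erna_toy"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
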