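import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module

from sats.ganet import GANetConfig
from sats.pipeline import SATSConfig
from sats.synthetic import generate_benchmark


@pytest.fixture()
def rng():
    return np.random.default_rng(20240828)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """2 source domains + target, 8 images each, 32x32 (cheap smoke data)."""
    return generate_benchmark(2, 8, 32, 32, master_seed=3)


@pytest.fixture()
def tiny_config():
    """A configuration small enough for second-scale training smoke tests."""
    return SATSConfig(ganet=GANetConfig(depth=2, base_channels=4),
                      epochs=5, batch_size=4, seed=5, ae_epochs=2)
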