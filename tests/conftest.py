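import numpy as np
import pytest

from radgs.qmaps import ParameterMap
from radgs.synthetic import default_phantom_config


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Phantom config on a small grid to keep map-fitting tests quick."""
    return default_phantom_config(seed=11, image_shape=(48, 48))


def make_map(grid, name="ADC", valid=None):
    grid = np.asarray(grid, dtype=float)
    if valid is None:
        valid = np.ones_like(grid, dtype=bool)
    return ParameterMap(name, grid, "um^2/ms", valid)
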