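import numpy as np
import pytest

from deserisk import GridLayer, canonical_config


@pytest.fixture(scope="session")
def config():
    return canonical_config()


@pytest.fixture
def small_layer():
    """3x3 layer with one masked cell."""
    values = np.arange(9, dtype=float).reshape(3, 3)
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    return GridLayer("demo", values, mask, cell_size=1.0)


def make_layer(values, name="layer", mask=None, cell_size=1.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return GridLayer(name, values, mask, cell_size=cell_size)
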