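import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_disk(shape=(64, 64), center=None, radius=15.0):
    """Boolean disk mask."""
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
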