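import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240607)


@pytest.fixture(scope="session")
def ring_image():
    """Grayscale ring: value 0.2 on an annulus, 0.9 elsewhere."""
    size = 21
    img = np.full((size, size), 0.9)
    yy, xx = np.mgrid[:size, :size] - size // 2
    r = np.hypot(yy, xx)
    img[(r >= 6) & (r <= 8)] = 0.2
    return img
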