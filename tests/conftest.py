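import numpy as np
import pytest


@pytest.fixture
def disk_mask():
    """Factory for a centered rasterized disk mask of given radius (px)."""

    def make(radius: int, margin: int = 5) -> np.ndarray:
        size = 2 * radius + 2 * margin
        yy, xx = np.indices((size, size))
        return np.hypot(yy - size / 2 + 0.5, xx - size / 2 + 0.5) <= radius

    return make


@pytest.fixture
def ellipse_mask():
    """Factory for a centered axis-aligned ellipse mask (semi-axes in px)."""

    def make(a: float, b: float, margin: int = 5) -> np.ndarray:
        size = int(2 * max(a, b)) + 2 * margin
        yy, xx = np.indices((size, size))
        return ((xx - size / 2 + 0.5) / a) ** 2 + ((yy - size / 2 + 0.5) / b) ** 2 <= 1

    return make


@pytest.fixture
def square_mask():
    def make(side: int, margin: int = 10) -> np.ndarray:
        size = side + 2 * margin
        m = np.zeros((size, size), dtype=bool)
        m[margin : margin + side, margin : margin + side] = True
        return m

    return make
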