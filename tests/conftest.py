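from __future__ import annotations

import numpy as np
import pytest

from texspec.core import texture_unit


def naive_histogram(img: np.ndarray, I: int, J: int) -> dict[int, int]:
    """Reference histogram: explicit double loop over window placements."""
    M, N = img.shape
    counts: dict[int, int] = {}
    for m in range(M - I + 1):
        for n in range(N - J + 1):
            k = texture_unit(img[m : m + I, n : n + J])
            counts[k] = counts.get(k, 0) + 1
    return counts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def checkerboard_4x4() -> np.ndarray:
    """Unit-cell checkerboard with a white top-left pixel."""
    r, c = np.indices((4, 4))
    return ((r + c) % 2 == 0).astype(np.uint8)
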