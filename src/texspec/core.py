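"""Row-coded texture units and the dimensional-space model.

An ``I x J`` binary pattern is encoded by reading each of its ``I`` rows as a
binary number (leftmost pixel = least-significant bit) and summing the ``I``
row codes.  The resulting integer ``k`` — the *texture unit* — therefore lies
in ``[0, I * (2**J - 1)]``, so a histogram indexed by ``k`` has

    K(I, J) = I * (2**J - 1) + 1

bins, far fewer than the ``2**(I*J)`` raw pattern states.  Windows from 3x3 up
to 10x10 keep ``K`` at or below 10,231 ("low" dimensional region); anything
with a side above 10 is "high".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ObservationWindow",
    "DimensionalSpace",
    "LOW_REGION_MAX_SIDE",
    "LOW_REGION_MIN_SIDE",
    "row_code",
    "texture_unit",
    "dimensional_space",
]

#: Inclusive side bounds of the low-dimensional window region.
LOW_REGION_MIN_SIDE = 3
LOW_REGION_MAX_SIDE = 10

#: Largest row width whose code still fits in a signed 64-bit integer.
MAX_ROW_BITS = 62


class ObservationWindow(NamedTuple):
    """Sliding-window shape: ``I`` rows by ``J`` columns."""

    I: int
    J: int

    def validate(self) -> "ObservationWindow":
        if int(self.I) < 1 or int(self.J) < 1:
            raise ValueError(
                f"observation window must have positive dimensions, got {self.I}x{self.J}"
            )
        return ObservationWindow(int(self.I), int(self.J))

    @property
    def K(self) -> int:
        """Number of attainable texture-unit values (histogram length)."""
        w = self.validate()
        return w.I * (2 ** w.J - 1) + 1


@dataclass(frozen=True)
class DimensionalSpace:
    """Histogram length ``K`` and the window-size region it falls in.

    ``region`` is ``"low"`` for windows 3x3..10x10 and ``"high"`` when either
    side exceeds 10.  Windows with a side below 3 are allowed (handy for
    testing) but flagged with ``undersized=True``; they are reported as
    ``"low"``.
    """

    K: int
    region: str
    undersized: bool = False


def _validate_bits(bits: np.ndarray) -> np.ndarray:
    arr = np.asarray(bits)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("pattern entries must be 0 or 1")
    return arr.astype(np.int64)


def row_code(bits: Sequence[int]) -> int:
    """Read one row of ``J`` bits as an integer in ``[0, 2**J - 1]``.

    The leftmost bit is the least-significant one, i.e.
    ``code = sum(b[j] * 2**j for j in range(J))``.

    >>> row_code([1, 0, 1])
    5
    """
    arr = _validate_bits(bits)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("row_code expects a non-empty 1-D bit row")
    if arr.size > MAX_ROW_BITS:
        raise ValueError(f"row width {arr.size} exceeds the {MAX_ROW_BITS}-bit limit")
    weights = 1 << np.arange(arr.size, dtype=np.int64)
    return int(arr @ weights)


def texture_unit(pattern: Sequence[Sequence[int]]) -> int:
    """Texture unit of an ``I x J`` binary pattern: the sum of its row codes.

    Row order does not matter (the sum is commutative), so the encoding
    collapses many distinct patterns onto each unit value.

    >>> texture_unit([[1, 0, 1], [0, 1, 0], [1, 1, 0]])
    10
    """
    arr = _validate_bits(pattern)
    if arr.ndim != 2:
        raise ValueError("pattern must be a rectangular I x J bit array")
    return sum(row_code(row) for row in arr)


def dimensional_space(window: ObservationWindow | tuple[int, int]) -> DimensionalSpace:
    """Histogram length and region classification for a window shape.

    ``K = I * (2**J - 1) + 1`` (exact integer arithmetic, any window size).
    """
    w = ObservationWindow(*window).validate()
    K = w.I * (2 ** w.J - 1) + 1
    undersized = w.I < LOW_REGION_MIN_SIDE or w.J < LOW_REGION_MIN_SIDE
    region = "high" if (w.I > LOW_REGION_MAX_SIDE or w.J > LOW_REGION_MAX_SIDE) else "low"
    return DimensionalSpace(K=K, region=region, undersized=undersized)
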