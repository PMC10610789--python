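"""Sliding-window texture histograms and spectra, plus the arithmetic cost model.

The window moves with stride 1 over all fully-interior positions of an
``M x N`` binary image, so exactly ``Pp = (M - I + 1) * (N - J + 1)`` units
are accumulated.  Normalizing the histogram by ``Pp`` gives the texture
spectrum, a probability vector over ``k = 0 .. K - 1`` used downstream as a
feature vector.

Histogram storage is dense (``numpy.bincount``) while ``K`` fits comfortably
in memory and a sparse unique-count map beyond that, so large windows such as
20x20 (``K`` ≈ 2.1e7) are handled without overflow; counts are 64-bit.  Both
backends are exact and interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import MAX_ROW_BITS, ObservationWindow

__all__ = [
    "TextureHistogram",
    "TextureSpectrum",
    "texture_histogram",
    "texture_spectrum",
    "count_operations",
    "DENSE_K_LIMIT",
]

#: Largest histogram length stored as a dense array by the "auto" backend.
DENSE_K_LIMIT = 2 ** 22

Backend = Literal["auto", "dense", "sparse"]


@dataclass(frozen=True)
class TextureHistogram:
    """Integer counts of texture units over all window placements.

    ``counts`` maps each attained unit ``k`` to its count (zero bins are
    omitted); ``total`` is the number of window placements ``Pp``.
    """

    window: ObservationWindow
    counts: Dict[int, int]
    total: int
    K: int = field(repr=False, default=0)

    def __post_init__(self) -> None:
        if self.K == 0:
            object.__setattr__(self, "K", self.window.K)

    def to_array(self) -> np.ndarray:
        """Dense count vector of length ``K`` (only sensible for small K)."""
        arr = np.zeros(self.K, dtype=np.int64)
        for k, c in self.counts.items():
            arr[k] = c
        return arr

    def normalize(self) -> "TextureSpectrum":
        probs = {k: c / self.total for k, c in self.counts.items()}
        return TextureSpectrum(window=self.window, probs=probs, K=self.K)


@dataclass(frozen=True)
class TextureSpectrum:
    """Normalized texture-unit histogram: ``probs[k] = counts[k] / Pp``."""

    window: ObservationWindow
    probs: Dict[int, float]
    K: int

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if self.probs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {total!r}, expected 1")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.K, dtype=float)
        for k, p in self.probs.items():
            arr[k] = p
        return arr


def _as_binary(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("image must be binary with values in {0, 1}")
    return arr.astype(np.int64)


def unit_map(img: np.ndarray, window: ObservationWindow | tuple[int, int]) -> np.ndarray:
    """Texture unit at every fully-interior window position.

    Returns an ``(M - I + 1) x (N - J + 1)`` int64 array.  Row codes are
    computed by correlating each image row with the weight vector
    ``(1, 2, 4, ...)`` and the unit is the vertical sum of ``I`` consecutive
    row codes — integer arithmetic throughout, bit-exact with the per-pattern
    definition.
    """
    arr = _as_binary(img)
    w = ObservationWindow(*window).validate()
    M, N = arr.shape
    if w.I > M or w.J > N:
        raise ValueError(
            f"window {w.I}x{w.J} does not fit inside a {M}x{N} image"
        )
    if w.J > MAX_ROW_BITS:
        raise ValueError(f"window width {w.J} exceeds the {MAX_ROW_BITS}-bit row limit")
    weights = 1 << np.arange(w.J, dtype=np.int64)
    # (M, N-J+1) row codes, then vertical sums of I consecutive codes.
    codes = sliding_window_view(arr, w.J, axis=1) @ weights
    units = sliding_window_view(codes, w.I, axis=0).sum(axis=2)
    return units


def texture_histogram(
    img: np.ndarray,
    window: ObservationWindow | tuple[int, int],
    backend: Backend = "auto",
) -> TextureHistogram:
    """Accumulate the texture-unit histogram of a binary image.

    Parameters
    ----------
    img : 2-D array of {0, 1}
    window : (I, J) window shape; must fit inside the image.
    backend : "dense" uses a length-``K`` bincount, "sparse" counts only the
        attained units, "auto" picks dense for ``K <= 2**22``.
    """
    w = ObservationWindow(*window).validate()
    units = unit_map(img, w)
    K = w.K
    if backend == "auto":
        backend = "dense" if K <= DENSE_K_LIMIT else "sparse"
    if backend == "dense":
        dense = np.bincount(units.ravel(), minlength=K)
        nz = np.nonzero(dense)[0]
        counts = {int(k): int(dense[k]) for k in nz}
    elif backend == "sparse":
        keys, vals = np.unique(units, return_counts=True)
        counts = {int(k): int(v) for k, v in zip(keys, vals)}
    else:
        raise ValueError(f"unknown histogram backend {backend!r}")
    return TextureHistogram(window=w, counts=counts, total=int(units.size), K=K)


def texture_spectrum(
    img: np.ndarray,
    window: ObservationWindow | tuple[int, int],
    backend: Backend = "auto",
) -> TextureSpectrum:
    """Normalized texture spectrum ``p(k) = h(k) / Pp`` of a binary image."""
    return texture_histogram(img, window, backend=backend).normalize()


def count_operations(M: int, N: int, window: ObservationWindow | tuple[int, int]) -> int:
    """Arithmetic operations needed to histogram an ``M x N`` image.

    Per pattern: ``I*J`` multiplications plus ``I*(J-1)`` additions for the
    row codes and ``I-1`` additions for the unit sum, i.e. ``2*I*J - 1``
    operations, over all ``(M-I+1)*(N-J+1)`` placements.
    """
    w = ObservationWindow(*window).validate()
    M, N = int(M), int(N)
    if w.I > M or w.J > N:
        raise ValueError(f"window {w.I}x{w.J} does not fit inside a {M}x{N} image")
    return (M - w.I + 1) * (N - w.J + 1) * (2 * w.I * w.J - 1)
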