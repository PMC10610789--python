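"""Shannon entropy of a texture spectrum and its equiprobable upper bound."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ObservationWindow
from .spectrum import TextureSpectrum

__all__ = ["TextureInformation", "entropy", "max_entropy"]


@dataclass(frozen=True)
class TextureInformation:
    """Entropy ``H`` of a spectrum in bits, with its length ``K`` and the
    equiprobable bound ``H_max = log2(K)``."""

    H: float
    K: int
    H_max: float


def entropy(spec: TextureSpectrum) -> TextureInformation:
    """Texture information ``H = -sum_k p(k) * log2 p(k)`` in bits.

    Zero-probability bins contribute nothing (``0 * log2 0 := 0``).  The
    spectrum must be normalized to 1 within 1e-9.
    """
    total = sum(spec.probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"spectrum is not normalized: sums to {total!r}")
    H = -sum(p * math.log2(p) for p in spec.probs.values() if p > 0.0)
    return TextureInformation(H=H, K=spec.K, H_max=math.log2(spec.K))


def max_entropy(window: ObservationWindow | tuple[int, int]) -> float:
    """Entropy (bits) of the equiprobable spectrum: ``log2(I*(2**J - 1) + 1)``.

    Strictly increasing in both window dimensions, hence the descriptor
    carries more texture information for larger windows.
    """
    w = ObservationWindow(*window).validate()
    return math.log2(w.K)
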