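"""Raster input and global-threshold binarization.

Images are loaded as 8-bit grayscale (RGB collapsed with Rec.601 luminance
weights) and turned into {0, 1} matrices by a single global threshold: a
pixel becomes 1 (white) iff its intensity is strictly greater than the
threshold, so ties go to black.  The default threshold is Otsu's — the
integer cut maximizing between-class variance.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "to_grayscale",
    "binarize_global",
    "otsu_threshold",
    "write_binary_image",
]

# Rec.601 luminance weights for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster image as an M x N uint8 grayscale array.

    PNG/PGM/PPM/TIFF/JPEG are accepted; RGB(A) inputs are converted with the
    Rec.601 weights (0.299, 0.587, 0.114), ignoring any alpha channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise OSError(f"could not read image {path}: {exc}") from exc
    return to_grayscale(raw)


def to_grayscale(raw: np.ndarray) -> np.ndarray:
    """Collapse a raster array to 2-D uint8 grayscale."""
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("image is empty")
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Integer threshold maximizing between-class variance.

    All cuts ``t`` in 0..254 splitting pixels into ``{<= t}`` vs ``{> t}``
    are scored; ties (e.g. plateaus between well-separated modes) are
    resolved by the midpoint of the maximizing range, as is conventional.
    """
    gray = np.asarray(img)
    if gray.size == 0:
        raise ValueError("cannot threshold an empty image")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(float)
    n = hist.sum()
    w0 = np.cumsum(hist)[:-1]            # pixels <= t, t = 0..254
    w1 = n - w0
    csum = np.cumsum(hist * np.arange(256))[:-1]
    mu0 = np.divide(csum, w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(csum[-1] + hist[255] * 255 - csum, w1,
                    out=np.zeros_like(w1), where=w1 > 0)
    var_b = w0 * w1 * (mu0 - mu1) ** 2
    best = np.flatnonzero(var_b == var_b.max())
    return int(round(best.mean()))


def binarize_global(
    img: np.ndarray,
    method: str = "otsu",
    threshold: int | None = None,
) -> np.ndarray:
    """Binarize a grayscale image with a global threshold.

    ``method="otsu"`` picks the threshold automatically; ``method="fixed"``
    requires ``threshold`` in [0, 255].  Output has the same shape, values in
    {0, 1}, with 1 = white (intensity strictly above the threshold).
    """
    gray = np.asarray(img)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("binarize_global expects a non-empty 2-D grayscale array")
    if method == "otsu":
        t = otsu_threshold(gray)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold binarization requires a threshold value")
        if not 0 <= threshold <= 255:
            raise ValueError(f"threshold {threshold} outside [0, 255]")
        t = int(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return (gray > t).astype(np.uint8)


def write_binary_image(path: str | Path, img: np.ndarray) -> None:
    """Write a {0, 1} matrix to disk as an 8-bit image (0 / 255)."""
    arr = np.asarray(img)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("write_binary_image expects values in {0, 1}")
    iio.imwrite(Path(path), (arr * 255).astype(np.uint8))
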