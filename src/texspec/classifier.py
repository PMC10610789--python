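"""Prototype-based multi-class texture classifier.

Learning: for every class image, draw ``n_train`` random subimages, compute
each subimage's texture spectrum, and average them into the class prototype
vector.  Recognition: build the test image's vector the same way from
``n_test`` subimages and assign the label of the prototype at minimum
distance (Euclidean by default; Manhattan and chi-squared available).
Evaluation over a labeled test set yields a confusion matrix whose diagonal
sum divided by the class count gives the efficiency percentage.

Randomness is explicit: the sampling seed lives in the config, learning uses
stream ``(seed, 0)`` and recognition stream ``(seed, 1)`` so train = test
protocols still draw independent subimages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import ObservationWindow
from .spectrum import TextureSpectrum, texture_spectrum

__all__ = [
    "SamplingConfig",
    "ClassPrototype",
    "ClassifierModel",
    "ConfusionMatrix",
    "sample_subimages",
    "learn",
    "classify",
    "evaluate",
    "efficiency",
    "spectrum_distance",
    "mean_spectrum",
    "DISTANCES",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Subimage sampling parameters for both classifier stages."""

    sub_rows: int
    sub_cols: int
    n_train: int = 100   # subimages per class in the learning stage
    n_test: int = 100    # subimages per image in the recognition stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sub_rows < 1 or self.sub_cols < 1:
            raise ValueError("subimage dimensions must be positive")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("subimage counts must be >= 1")


@dataclass(frozen=True)
class ClassPrototype:
    label: str
    spectrum: TextureSpectrum


@dataclass(frozen=True)
class ClassifierModel:
    window: ObservationWindow
    prototypes: List[ClassPrototype]
    distance: str
    sampling: SamplingConfig

    @property
    def labels(self) -> List[str]:
        return [p.label for p in self.prototypes]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = true (test) classes, columns = predicted (prototype) classes."""

    labels: List[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.int64)
        C = len(self.labels)
        if arr.shape != (C, C):
            raise ValueError(f"confusion matrix must be {C}x{C}, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "entries", arr)


def _dist_euclidean(a: Dict[int, float], b: Dict[int, float]) -> float:
    keys = a.keys() | b.keys()
    return float(np.sqrt(sum((a.get(k, 0.0) - b.get(k, 0.0)) ** 2 for k in keys)))


def _dist_manhattan(a: Dict[int, float], b: Dict[int, float]) -> float:
    keys = a.keys() | b.keys()
    return float(sum(abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in keys))


def _dist_chi2(a: Dict[int, float], b: Dict[int, float]) -> float:
    keys = a.keys() | b.keys()
    total = 0.0
    for k in keys:
        pa, pb = a.get(k, 0.0), b.get(k, 0.0)
        if pa + pb > 0:
            total += (pa - pb) ** 2 / (pa + pb)
    return 0.5 * total


DISTANCES = {
    "euclidean": _dist_euclidean,
    "manhattan": _dist_manhattan,
    "chi2": _dist_chi2,
}


def spectrum_distance(a: TextureSpectrum, b: TextureSpectrum, metric: str = "euclidean") -> float:
    """Distance between two spectra over the union of their supports."""
    if a.K != b.K:
        raise ValueError(f"spectra live in different spaces: K={a.K} vs K={b.K}")
    try:
        fn = DISTANCES[metric]
    except KeyError:
        raise ValueError(f"unknown distance metric {metric!r}") from None
    return fn(a.probs, b.probs)


def mean_spectrum(spectra: Sequence[TextureSpectrum]) -> TextureSpectrum:
    """Arithmetic mean of normalized spectra (itself normalized)."""
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    K = spectra[0].K
    window = spectra[0].window
    if any(s.K != K for s in spectra):
        raise ValueError("all spectra must share one dimensional space")
    acc: Dict[int, float] = {}
    for s in spectra:
        for k, p in s.probs.items():
            acc[k] = acc.get(k, 0.0) + p
    n = len(spectra)
    probs = {k: v / n for k, v in acc.items()}
    return TextureSpectrum(window=window, probs=probs, K=K)


def sample_subimages(
    img: np.ndarray,
    cfg: SamplingConfig,
    count: int,
    rng: np.random.Generator | None = None,
) -> List[np.ndarray]:
    """Draw ``count`` subimages with uniformly random top-left corners.

    Sampling is with replacement over all fully-interior positions; with
    ``rng`` omitted a fresh generator seeded from ``cfg.seed`` is used, so
    repeated calls with the same arguments return identical corner sequences.
    """
    arr = np.asarray(img)
    M, N = arr.shape
    if cfg.sub_rows > M or cfg.sub_cols > N:
        raise ValueError(
            f"subimage {cfg.sub_rows}x{cfg.sub_cols} does not fit inside a {M}x{N} image"
        )
    if count < 0:
        raise ValueError("count must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    max_r = M - cfg.sub_rows + 1
    max_c = N - cfg.sub_cols + 1
    rows = rng.integers(0, max_r, size=count)
    cols = rng.integers(0, max_c, size=count)
    return [
        arr[r : r + cfg.sub_rows, c : c + cfg.sub_cols]
        for r, c in zip(rows, cols)
    ]


def _image_vector(
    img: np.ndarray,
    window: ObservationWindow,
    cfg: SamplingConfig,
    count: int,
    rng: np.random.Generator,
) -> TextureSpectrum:
    subs = sample_subimages(img, cfg, count, rng=rng)
    return mean_spectrum([texture_spectrum(s, window) for s in subs])


def learn(
    class_images: Sequence[Tuple[str, np.ndarray]],
    window: ObservationWindow | tuple[int, int],
    cfg: SamplingConfig,
    distance: str = "euclidean",
) -> ClassifierModel:
    """Build one prototype per class from ``cfg.n_train`` random subimages."""
    w = ObservationWindow(*window).validate()
    if len(class_images) < 2:
        raise ValueError("learning requires at least 2 classes")
    labels = [label for label, _ in class_images]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate class labels: {labels}")
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance metric {distance!r}")
    rng = np.random.default_rng([cfg.seed, 0])
    prototypes = [
        ClassPrototype(label, _image_vector(img, w, cfg, cfg.n_train, rng))
        for label, img in class_images
    ]
    return ClassifierModel(window=w, prototypes=prototypes, distance=distance, sampling=cfg)


def classify(
    test_img: np.ndarray,
    model: ClassifierModel,
    rng: np.random.Generator | None = None,
) -> Tuple[str, Dict[str, float]]:
    """Assign the minimum-distance prototype label to a test image.

    Returns ``(label, {class: distance})``.  Ties go to the earliest class in
    model order.  With ``rng`` omitted the recognition stream
    ``(sampling.seed, 1)`` is used, keeping results deterministic while
    independent of the learning stage's draws.
    """
    if rng is None:
        rng = np.random.default_rng([model.sampling.seed, 1])
    vector = _image_vector(
        test_img, model.window, model.sampling, model.sampling.n_test, rng
    )
    fn = DISTANCES[model.distance]
    distances = {p.label: fn(vector.probs, p.spectrum.probs) for p in model.prototypes}
    best = min(model.labels, key=lambda lab: distances[lab])  # stable: model order
    return best, distances


def evaluate(
    model: ClassifierModel,
    test_images: Sequence[Tuple[str, np.ndarray]],
) -> ConfusionMatrix:
    """Classify a labeled test set into a confusion matrix (one decision per image)."""
    index = {label: i for i, label in enumerate(model.labels)}
    C = len(index)
    entries = np.zeros((C, C), dtype=np.int64)
    rng = np.random.default_rng([model.sampling.seed, 1])
    for label, img in test_images:
        if label not in index:
            raise ValueError(f"test label {label!r} is not a model class")
        predicted, _ = classify(img, model, rng=rng)
        entries[index[label], index[predicted]] += 1
    return ConfusionMatrix(labels=list(model.labels), entries=entries)


def efficiency(mc: ConfusionMatrix) -> float:
    """Percentage of correct decisions: ``100 * trace / C`` with one test
    image per class."""
    C = len(mc.labels)
    return float(np.trace(mc.entries)) / C * 100.0
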