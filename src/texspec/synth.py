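"""Seeded synthetic binary textures for exercising spectra and the classifier.

Four texture families cover the interesting regimes of the descriptor:
constant-ish fields (near-delta spectra), checkerboards and stripes
(few-state periodic spectra), Bernoulli noise (broad spectra) and smoothed
thresholded noise ("blob" fields, spatially correlated).  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Tuple

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["TextureSpec", "make_texture", "make_database", "default_grid"]


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic binary texture."""

    kind: str                      # bernoulli | checkerboard | stripes | blob
    rows: int
    cols: int
    seed: int = 0
    params: Dict[str, Any] = field(default_factory=dict)


def _bernoulli(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    p = float(spec.params.get("p", 0.5))
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bernoulli density {p} outside [0, 1]")
    return (rng.random((spec.rows, spec.cols)) < p).astype(np.uint8)


def _checkerboard(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    cell = int(spec.params.get("cell", 1))
    if cell < 1:
        raise ValueError(f"checkerboard cell size must be >= 1, got {cell}")
    r = np.arange(spec.rows)[:, None] // cell
    c = np.arange(spec.cols)[None, :] // cell
    return (((r + c) % 2) == 0).astype(np.uint8)  # top-left cell is white


def _stripes(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    width = int(spec.params.get("width", 2))
    orientation = spec.params.get("orientation", "horizontal")
    if width < 1:
        raise ValueError(f"stripe width must be >= 1, got {width}")
    r = np.arange(spec.rows)[:, None]
    c = np.arange(spec.cols)[None, :]
    if orientation == "horizontal":
        phase = r // width
    elif orientation == "vertical":
        phase = c // width
    elif orientation == "diagonal":
        phase = (r + c) // width
    else:
        raise ValueError(f"unknown stripe orientation {orientation!r}")
    return ((phase % 2) == 0).astype(np.uint8) * np.ones((spec.rows, spec.cols), np.uint8)


def _blob(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    radius = int(spec.params.get("radius", 3))
    quantile = float(spec.params.get("quantile", 0.5))
    if radius < 1:
        raise ValueError(f"blob radius must be >= 1, got {radius}")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"blob quantile {quantile} outside (0, 1)")
    noise = rng.random((spec.rows, spec.cols))
    smooth = uniform_filter(noise, size=2 * radius + 1, mode="wrap")
    return (smooth > np.quantile(smooth, quantile)).astype(np.uint8)


_KINDS = {
    "bernoulli": _bernoulli,
    "checkerboard": _checkerboard,
    "stripes": _stripes,
    "blob": _blob,
}


def make_texture(spec: TextureSpec) -> np.ndarray:
    """Render a spec to a ``rows x cols`` uint8 array over {0, 1}."""
    if spec.rows < 1 or spec.cols < 1:
        raise ValueError(f"texture size must be positive, got {spec.rows}x{spec.cols}")
    try:
        gen = _KINDS[spec.kind]
    except KeyError:
        raise ValueError(
            f"unknown texture kind {spec.kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    return gen(spec, np.random.default_rng(spec.seed))


def default_grid() -> List[Tuple[str, Dict[str, Any]]]:
    """Ordered parameter grid the class database draws from.

    Entries are chosen pairwise-distinct and well separated so the resulting
    spectra are easy to tell apart.
    """
    return [
        ("bernoulli", {"p": 0.1}),
        ("bernoulli", {"p": 0.9}),
        ("checkerboard", {"cell": 1}),
        ("stripes", {"width": 2, "orientation": "horizontal"}),
        ("bernoulli", {"p": 0.3}),
        ("stripes", {"width": 3, "orientation": "vertical"}),
        ("bernoulli", {"p": 0.7}),
        ("blob", {"radius": 2, "quantile": 0.5}),
        ("checkerboard", {"cell": 3}),
        ("stripes", {"width": 2, "orientation": "diagonal"}),
        ("bernoulli", {"p": 0.5}),
        ("blob", {"radius": 4, "quantile": 0.35}),
        ("bernoulli", {"p": 0.2}),
        ("checkerboard", {"cell": 2}),
        ("stripes", {"width": 3, "orientation": "horizontal"}),
        ("bernoulli", {"p": 0.8}),
        ("blob", {"radius": 3, "quantile": 0.65}),
        ("stripes", {"width": 4, "orientation": "vertical"}),
        ("bernoulli", {"p": 0.4}),
        ("checkerboard", {"cell": 5}),
    ]


def _hard_grid(C: int) -> List[Tuple[str, Dict[str, Any]]]:
    # Bernoulli fields with nearly identical densities: barely separable at
    # small windows, cleaner at larger ones.
    densities = np.linspace(0.495, 0.505, C)
    return [("bernoulli", {"p": round(float(p), 6)}) for p in densities]


def make_database(
    C: int,
    rows: int,
    cols: int,
    seed: int = 0,
    hard: bool = False,
) -> List[Tuple[str, np.ndarray]]:
    """Generate ``C`` labeled class images with pairwise-distinct parameters.

    Labels are ``class_01`` .. ``class_C``.  ``hard=True`` swaps the spread
    parameter grid for closely spaced noise densities, producing classes that
    small observation windows genuinely confuse.
    """
    if C < 2:
        raise ValueError(f"a class database needs at least 2 classes, got {C}")
    grid = _hard_grid(C) if hard else default_grid()
    if C > len(grid):
        raise ValueError(f"requested {C} classes but the parameter grid has {len(grid)}")
    ss = np.random.SeedSequence(seed).spawn(C)
    database = []
    for idx in range(C):
        kind, params = grid[idx]
        child_seed = int(ss[idx].generate_state(1)[0])
        spec = TextureSpec(kind=kind, rows=rows, cols=cols, seed=child_seed, params=params)
        database.append((f"class_{idx + 1:02d}", make_texture(spec)))
    return database
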