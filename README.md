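# texspec

Texture descriptors for binary images built from a *row-coded texture unit*:
each row of an `I x J` observation window is read as a binary number
(leftmost pixel = least-significant bit) and the row codes are summed.  The
unit `k` therefore ranges over only `K = I * (2**J - 1) + 1` values instead
of `2**(I*J)` raw pattern states, which keeps the sliding-window histogram —
the *texture spectrum* — small enough to use as a feature vector even for
large windows.

The package provides:

- **`texspec.binarize`** — raster input (PNG/PGM/TIFF/JPEG), Rec.601
  grayscale conversion, and global thresholding (Otsu or fixed; a pixel is
  white iff strictly above the threshold).
- **`texspec.core`** — the row code, the texture unit, and the
  dimensional-space model `K(I, J)` with its low (3x3..10x10) / high
  (side > 10) window regions.
- **`texspec.spectrum`** — stride-1 fully-interior sliding-window
  histograms and normalized spectra, with dense and sparse storage backends
  (20x20 windows and beyond work without overflow), plus the arithmetic
  operation-count model `(M-I+1)(N-J+1)(2IJ-1)`.
- **`texspec.information`** — Shannon entropy of a spectrum in bits and its
  equiprobable bound `log2 K`.
- **`texspec.classifier`** — the subimage-sampling multi-class classifier:
  per-class prototype spectra averaged over randomly drawn subimages,
  minimum-distance assignment (Euclidean / Manhattan / chi-squared),
  confusion matrices and the efficiency percentage `100 * trace / C`.
- **`texspec.synth`** — seeded synthetic binary texture classes (Bernoulli
  noise, checkerboards, stripes, smoothed blobs), including a deliberately
  hard variant with closely spaced noise densities.

## CLI

All functionality is exposed through a single `texspec` entry point:

```sh
# Histogram length / region / entropy bound for a window size
texspec info --window 5 5

# Arithmetic-operation count of one histogram computation
texspec ops --rows 300 --cols 300 --window 3 3     # -> 1509668

# Texture spectrum of an image (sparse CSV + JSON sidecar)
texspec spectrum tile.png --window 5 5 --out tile_spectrum.csv

# Texture information in bits, from an image or a saved spectrum
texspec entropy tile.png --window 5 5
texspec entropy --spectrum-csv tile_spectrum.csv

# Synthetic class database -> train -> classify / evaluate
texspec synth --out db/ --classes 12 --rows 300 --cols 300 --seed 1
texspec train db/ --window 5 5 --sub-rows 150 --sub-cols 150 \
    --n-train 100 --n-test 100 --seed 1 --out model.json
texspec classify model.json db/class_01.png
texspec evaluate model.json db/ --out confusion.csv
```

`train` and `spectrum` also accept `--config FILE` with `key=value` lines
(`window_i`, `sub_rows`, `seed`, ...); explicit flags win over the file.

## Conventions

- Binary images are `{0, 1}` numpy arrays with 1 = white.
- Row bits are read left-to-right as least-to-most significant; any fixed
  orientation yields an equivalent descriptor (a relabeling of `k`).
- Windows are fully interior with stride 1, so a spectrum is normalized by
  `(M - I + 1) * (N - J + 1)`.
- Thresholding ties map to black; Otsu ties resolve to the midpoint of the
  maximizing plateau.
- All sampling randomness flows from an explicit seed; learning and
  recognition use separate derived streams so train = test protocols still
  draw independent subimages.
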