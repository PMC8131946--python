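"""Damage simulators and download-free test fixtures.

The restoration benchmark needs controlled damage: regions of a binary
image overwritten with a uniform mid-grey (intensity 128, i.e. phase close
to 0 — neither ink nor background).  Damage is non-blind: every simulator
returns the boolean mask of overwritten cells, which becomes the inpainting
domain D.

Three families are provided, mirroring the benchmark protocol:

* ``damage_customized`` — deterministic line damage in four fashions
  (A: thin vertical line, B: two vertical lines, C: thick horizontal band,
  the most destructive, D: thin horizontal line);
* ``damage_random_rows`` / ``damage_random_pixels`` — seeded random damage
  of increasing intensity (k whole rows, or a fraction p of all pixels);
* fixtures: ``make_cross_line`` (the classic 50x50 vertical bar crossed by
  a grey band, used to tune eps and lambda) and ``make_glyph_dataset``
  (28x28 binary digit glyphs rendered from a built-in 5x7 bitmap font with
  seeded jitter, standing in for handwritten-digit data in self-contained
  tests; synthetic by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phasefield import ConfigError

__all__ = [
    "DamageResult",
    "GREY",
    "make_cross_line",
    "damage_customized",
    "damage_random_rows",
    "damage_random_pixels",
    "make_glyph_dataset",
    "CUSTOM_KINDS",
]

#: Intensity written into damaged cells: mid-grey between black and white,
#: mapping to phase 2*(128/255) - 1 ~ 0.004.
GREY = 128

CUSTOM_KINDS = ("A", "B", "C", "D")


@dataclass
class DamageResult:
    """A damaged 8-bit image plus the mask of the inpainting domain."""

    image: np.ndarray  # uint8, damaged copy
    mask: np.ndarray  # bool, True = overwritten cell (inpainting domain D)
    kind: str
    intensity: float | int | None = None
    seed: int | None = None

    @property
    def n_damaged(self) -> int:
        return int(np.count_nonzero(self.mask))


def _as_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D greyscale image, got shape {img.shape}")
    return img.astype(np.uint8, copy=True)


def make_cross_line(
    n: int = 50, *, bar_width: int = 6, band_height: int = 10
) -> tuple[np.ndarray, DamageResult]:
    """Cross-line fixture: vertical black bar crossed by a grey damage band.

    Returns the clean ``n x n`` binary image (white background 255, black
    bar 0 — drawn in intensity space; the bar is the ink phase) and a
    :class:`DamageResult` whose damaged copy has a centred horizontal
    mid-grey band covering the bar.  Used to calibrate eps and lambda.
    """
    if n < 20:
        raise ConfigError(f"cross-line fixture needs n >= 20, got {n}")
    if bar_width >= n or band_height >= n:
        raise ConfigError("bar/band do not fit in the image")
    clean = np.zeros((n, n), dtype=np.uint8)  # background 0
    c0 = (n - bar_width) // 2
    clean[:, c0 : c0 + bar_width] = 255  # vertical ink bar
    r0 = (n - band_height) // 2
    damaged = clean.copy()
    damaged[r0 : r0 + band_height, :] = GREY
    mask = np.zeros((n, n), dtype=bool)
    mask[r0 : r0 + band_height, :] = True
    return clean, DamageResult(image=damaged, mask=mask, kind="cross_line", intensity=band_height)


def _scaled(extent: int, size: int, base: int = 28) -> int:
    """Scale a default geometry extent proportionally for non-28 sizes."""
    return max(1, round(extent * size / base))


def damage_customized(image: np.ndarray, kind: str) -> DamageResult:
    """Deterministic line damage of one of four fashions A-D.

    A: thin vertical line (2 columns, centred); B: two vertical lines
    (2 columns each at 1/3 and 2/3 of the width); C: thick horizontal band
    (6 rows, centred; the most destructive); D: thin horizontal line
    (2 rows, centred).  Geometry scales proportionally for images that are
    not 28x28.
    """
    if kind not in CUSTOM_KINDS:
        raise ValueError(f"unknown customized damage kind {kind!r}; expected one of {CUSTOM_KINDS}")
    img = _as_u8(image)
    ny, nx = img.shape
    mask = np.zeros_like(img, dtype=bool)
    if kind == "A":
        w = _scaled(2, nx)
        c = (nx - w) // 2
        mask[:, c : c + w] = True
    elif kind == "B":
        w = _scaled(2, nx)
        for frac in (1 / 3, 2 / 3):
            c = int(round(frac * nx)) - w // 2
            c = min(max(c, 0), nx - w)
            mask[:, c : c + w] = True
    elif kind == "C":
        h = _scaled(6, ny)
        r = (ny - h) // 2
        mask[r : r + h, :] = True
    else:  # D
        h = _scaled(2, ny)
        r = (ny - h) // 2
        mask[r : r + h, :] = True
    img[mask] = GREY
    return DamageResult(image=img, mask=mask, kind=f"custom_{kind}")


def damage_random_rows(image: np.ndarray, k: int, seed: int) -> DamageResult:
    """Overwrite ``k`` distinct rows (chosen uniformly at random) with mid-grey."""
    img = _as_u8(image)
    ny = img.shape[0]
    if not (0 <= k <= ny):
        raise ValueError(f"row count k={k} out of range [0, {ny}]")
    rng = np.random.default_rng(seed)
    rows = rng.choice(ny, size=k, replace=False)
    mask = np.zeros_like(img, dtype=bool)
    mask[rows, :] = True
    img[mask] = GREY
    return DamageResult(image=img, mask=mask, kind="rows", intensity=k, seed=seed)


def damage_random_pixels(image: np.ndarray, p: float, seed: int) -> DamageResult:
    """Overwrite a fraction ``p`` of all pixels (without replacement) with mid-grey."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"pixel fraction p={p} out of range [0, 1]")
    img = _as_u8(image)
    n_cells = img.size
    n_pick = int(round(p * n_cells))
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_pick, replace=False)
    mask = np.zeros(n_cells, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(img.shape)
    img[mask] = GREY
    return DamageResult(image=img, mask=mask, kind="pixels", intensity=p, seed=seed)


# --- synthetic digit glyphs --------------------------------------------------

# Classic 5x7 dot-matrix digit bitmaps.
_FONT = {
    0: ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    1: ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    3: ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    4: ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    6: ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    7: ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    8: ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    9: ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
}


def _glyph_bitmap(digit: int, scale: int = 3) -> np.ndarray:
    rows = _FONT[digit]
    bits = np.array([[c == "1" for c in row] for row in rows], dtype=bool)
    return np.kron(bits, np.ones((scale, scale), dtype=bool))


def make_glyph_dataset(
    n_per_class: int, seed: int, *, size: int = 28
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 28x28 binary digit images from a built-in bitmap font.

    Renders each digit 0-9 at 3x scale (21x15 pixels), pastes it near the
    centre of a ``size x size`` canvas with a seeded random translation of
    up to 2 pixels per axis, and with probability 1/2 thickens the strokes
    by one pixel of binary dilation.  Intensities are exactly {0, 255},
    labels are balanced.  Deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    images = np.zeros((10 * n_per_class, size, size), dtype=np.uint8)
    labels = np.zeros(10 * n_per_class, dtype=np.int64)
    idx = 0
    for digit in range(10):
        base = _glyph_bitmap(digit)
        gh, gw = base.shape
        r0 = (size - gh) // 2
        c0 = (size - gw) // 2
        for _ in range(n_per_class):
            bits = base
            if rng.random() < 0.5:
                bits = ndimage.binary_dilation(bits)
            dr, dc = rng.integers(-2, 3, size=2)
            canvas = np.zeros((size, size), dtype=bool)
            canvas[r0 + dr : r0 + dr + gh, c0 + dc : c0 + dc + gw] = bits
            images[idx] = np.where(canvas, 255, 0).astype(np.uint8)
            labels[idx] = digit
            idx += 1
    return images, labels
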