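"""Raster I/O and the intensity <-> phase mapping contract.

The solver works on phase fields in [-1, 1]; images are stored as 8-bit
intensities.  The fixed mapping is ``phi = 2*(I/255) - 1``: background 0
maps to phase -1, ink 255 to +1, the mid-grey damage value 128 to ~0.004.
The inverse clips to [-1, 1] before quantizing, so solver overshoots export
cleanly.

Containers: the big-endian IDX format (the handwritten-digit dataset
dialect: magic 2051 for images, 2049 for labels) and binary PGM (P5,
maxval 255).  All round trips are bit-exact and malformed headers raise
typed errors.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phasefield import PhaseField

__all__ = [
    "LabeledImageSet",
    "FormatError",
    "ConsistencyError",
    "read_idx",
    "write_idx",
    "read_pgm",
    "write_pgm",
    "intensity_to_phase",
    "phase_to_intensity",
]

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


class FormatError(ValueError):
    """A file does not conform to the expected raster format."""


class ConsistencyError(ValueError):
    """Paired files disagree (e.g. image and label counts)."""


@dataclass
class LabeledImageSet:
    """A stack of same-shape 8-bit images with integer labels 0-9."""

    images: np.ndarray  # (n, rows, cols) uint8
    labels: np.ndarray  # (n,) int
    source: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n, rows, cols), got shape {self.images.shape}")
        if len(self.images) != len(self.labels):
            raise ConsistencyError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.images)


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise IOError(f"truncated IDX payload while reading {what}: wanted {n} bytes, got {len(buf)}")
    return buf


def read_idx(images_path, labels_path, source: str | None = None) -> LabeledImageSet:
    """Read a paired big-endian IDX image/label file set."""
    images_path, labels_path = Path(images_path), Path(labels_path)
    with open(images_path, "rb") as fh:
        magic, count, rows, cols = struct.unpack(">iiii", _read_exact(fh, 16, "image header"))
        if magic != _IDX_IMAGES_MAGIC:
            raise FormatError(f"{images_path}: bad image magic {magic}, expected {_IDX_IMAGES_MAGIC}")
        payload = _read_exact(fh, count * rows * cols, "image data")
        images = np.frombuffer(payload, dtype=np.uint8).reshape(count, rows, cols)
    with open(labels_path, "rb") as fh:
        magic, lcount = struct.unpack(">ii", _read_exact(fh, 8, "label header"))
        if magic != _IDX_LABELS_MAGIC:
            raise FormatError(f"{labels_path}: bad label magic {magic}, expected {_IDX_LABELS_MAGIC}")
        if lcount != count:
            raise ConsistencyError(f"image count {count} != label count {lcount}")
        labels = np.frombuffer(_read_exact(fh, lcount, "label data"), dtype=np.uint8)
    return LabeledImageSet(
        images=images.copy(),
        labels=labels.astype(np.int64),
        source=source or str(images_path),
    )


def write_idx(dataset: LabeledImageSet, images_path, labels_path) -> None:
    """Write a labelled image set as a paired big-endian IDX file set."""
    n = len(dataset)
    rows, cols = (dataset.images.shape[1:] if n else (0, 0))
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(dataset.images.astype(np.uint8).tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABELS_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())


def read_pgm(path) -> np.ndarray:
    """Read a binary (P5) PGM image with maxval <= 255."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:2] != b"P5":
        raise FormatError(f"{path}: not a binary PGM (P5) file")
    # header tokens: magic, width, height, maxval; comments start with '#'
    tokens: list[bytes] = []
    pos = 2
    while len(tokens) < 3 and pos < len(data):
        while pos < len(data) and data[pos : pos + 1].isspace():
            pos += 1
        if data[pos : pos + 1] == b"#":
            while pos < len(data) and data[pos : pos + 1] != b"\n":
                pos += 1
            continue
        start = pos
        while pos < len(data) and not data[pos : pos + 1].isspace():
            pos += 1
        tokens.append(data[start:pos])
    if len(tokens) < 3:
        raise FormatError(f"{path}: truncated PGM header")
    try:
        width, height, maxval = (int(t) for t in tokens)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed PGM header") from exc
    if maxval > 255 or maxval < 1:
        raise FormatError(f"{path}: unsupported PGM maxval {maxval}")
    pos += 1  # single whitespace after maxval
    pixels = data[pos : pos + width * height]
    if len(pixels) != width * height:
        raise IOError(f"{path}: truncated PGM payload")
    return np.frombuffer(pixels, dtype=np.uint8).reshape(height, width).copy()


def write_pgm(path, image: np.ndarray) -> None:
    """Write an 8-bit greyscale image as binary PGM (P5, maxval 255)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"PGM images are 2-D, got shape {img.shape}")
    img = img.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(f"P5\n{img.shape[1]} {img.shape[0]}\n255\n".encode())
        fh.write(img.tobytes())


def intensity_to_phase(image: np.ndarray, dx: float = 1.0, dy: float = 1.0) -> PhaseField:
    """Map 8-bit intensities to a phase field: ``phi = 2*(I/255) - 1``."""
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return PhaseField(2.0 * (img / 255.0) - 1.0, dx, dy)


def phase_to_intensity(fld: PhaseField | np.ndarray) -> np.ndarray:
    """Map a phase field back to 8-bit intensities, clipping to [-1, 1]."""
    values = fld.values if isinstance(fld, PhaseField) else np.asarray(fld, dtype=float)
    clipped = np.clip(values, -1.0, 1.0)
    return np.round(255.0 * (clipped + 1.0) / 2.0).astype(np.uint8)
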