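"""Synthetic glyph corpus generation and IDX container I/O.

The generator emulates the statistical structure of a handwritten-digit set:
10 visually distinct glyph classes rasterized at 28x28, with per-"writer"
style variation (each writer is a fixed affine jitter + stroke-width choice
drawn once) and per-image Gaussian pixel noise.  Glyphs are stored dark-on-
light: ink is near 0, background is 1.

The IDX reader/writer lets users substitute a real handwritten-digit set
stored in the standard big-endian IDX container; nothing else in the package
depends on it.
"""

from __future__ import annotations

import dataclasses
import struct

import numpy as np
from scipy import ndimage

UNKNOWN_WRITER = -1

#: seven-segment layout (row/col spans on the 28x28 canvas, half-open).
#: Strokes are 3 px so class differences survive two rounds of 2x2 average
#: pooling, matching the coarse separability of real handwriting.
_SEGMENTS = {
    "a": (slice(3, 6), slice(6, 22)),     # top bar
    "g": (slice(12, 15), slice(6, 22)),   # middle bar
    "d": (slice(21, 24), slice(6, 22)),   # bottom bar
    "f": (slice(3, 15), slice(6, 9)),     # upper left
    "b": (slice(3, 15), slice(19, 22)),   # upper right
    "e": (slice(12, 24), slice(6, 9)),    # lower left
    "c": (slice(12, 24), slice(19, 22)),  # lower right
}

_DIGIT_SEGMENTS = {
    0: "abcdef",
    1: "bc",
    2: "abged",
    3: "abgcd",
    4: "fgbc",
    5: "afgcd",
    6: "afgedc",
    7: "abc",
    8: "abcdefg",
    9: "abcfgd",
}


class IdxFormatError(ValueError):
    """Raised when an IDX file violates the container format."""


@dataclasses.dataclass
class GlyphCorpus:
    """Labeled 28x28 glyph images with writer provenance.

    ``images`` are float32 in [0, 1]; ``polarity`` records whether ink is
    dark on a light background (the convention used throughout) or inverted.
    """

    images: np.ndarray
    labels: np.ndarray
    writer_ids: np.ndarray
    polarity: str = "dark_on_light"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.writer_ids = np.asarray(self.writer_ids, dtype=np.int64)
        if not (len(self.images) == len(self.labels) == len(self.writer_ids)):
            raise ValueError("images, labels and writer_ids must have equal length")
        if self.polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def __len__(self) -> int:
        return len(self.images)

    def class_indices(self, digit: int) -> np.ndarray:
        return np.flatnonzero(self.labels == digit)

    def subset(self, idx) -> "GlyphCorpus":
        return GlyphCorpus(
            self.images[idx], self.labels[idx], self.writer_ids[idx], self.polarity
        )


def _digit_template(digit: int) -> np.ndarray:
    ink = np.zeros((28, 28), dtype=np.float32)
    for seg in _DIGIT_SEGMENTS[digit]:
        ink[_SEGMENTS[seg]] = 1.0
    return ink


@dataclasses.dataclass(frozen=True)
class _WriterStyle:
    angle: float      # degrees
    shear: float
    shift: tuple      # (rows, cols), pixels
    dilate: int       # structuring-element size (1 = none)
    noise_sd: float


def _draw_writer_styles(n_writers: int, rng: np.random.Generator):
    styles = []
    for _ in range(n_writers):
        styles.append(
            _WriterStyle(
                angle=float(rng.uniform(-15, 15)),
                shear=float(rng.uniform(-0.15, 0.15)),
                shift=(int(rng.integers(-2, 3)), int(rng.integers(-2, 3))),
                dilate=int(rng.integers(1, 3)),
                noise_sd=0.05,
            )
        )
    return styles


def _styled_glyph(digit: int, style: _WriterStyle) -> np.ndarray:
    """Apply a writer's fixed affine + stroke style to a digit template."""
    ink = _digit_template(digit)
    theta = np.deg2rad(style.angle)
    fwd = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    ) @ np.array([[1.0, style.shear], [0.0, 1.0]])
    inv = np.linalg.inv(fwd)
    center = np.array([13.5, 13.5])
    offset = center - inv @ (center + np.asarray(style.shift, dtype=float))
    out = ndimage.affine_transform(ink, inv, offset=offset, order=1, cval=0.0)
    if style.dilate > 1:
        out = ndimage.grey_dilation(out, size=(style.dilate, style.dilate))
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def make_glyph_corpus(n_per_class: int, n_writers: int, seed: int) -> GlyphCorpus:
    """Generate ``10 * n_per_class`` glyphs with round-robin writer assignment.

    Writer styles are drawn once from the seed; images of the same
    (class, writer) pair share a styled template and differ only by the
    per-image pixel noise, which is how repeated exemplars from one writer
    behave in a handwriting pool.
    """
    if n_per_class < 1 or n_writers < 1:
        raise ValueError("n_per_class and n_writers must be positive")
    rng = np.random.default_rng(seed)
    styles = _draw_writer_styles(n_writers, rng)
    n = 10 * n_per_class
    images = np.empty((n, 28, 28), dtype=np.float32)
    labels = np.empty(n, dtype=np.int64)
    writers = np.empty(n, dtype=np.int64)
    base_cache: dict = {}
    row = 0
    for digit in range(10):
        for i in range(n_per_class):
            w = i % n_writers
            key = (digit, w)
            if key not in base_cache:
                base_cache[key] = _styled_glyph(digit, styles[w])
            ink = base_cache[key] + rng.normal(0.0, styles[w].noise_sd, (28, 28))
            images[row] = 1.0 - np.clip(ink, 0.0, 1.0)
            labels[row] = digit
            writers[row] = w
            row += 1
    return GlyphCorpus(images, labels, writers, "dark_on_light")


def split_corpus(corpus: GlyphCorpus, holdout_fraction: float, seed: int):
    """Disjoint, class-stratified split into (main, holdout)."""
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    main_idx, hold_idx = [], []
    for digit in range(10):
        idx = corpus.class_indices(digit)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(len(idx) * holdout_fraction))
        hold_idx.append(idx[:k])
        main_idx.append(idx[k:])
    main_idx = np.sort(np.concatenate(main_idx))
    hold_idx = np.sort(np.concatenate(hold_idx))
    return corpus.subset(main_idx), corpus.subset(hold_idx)


# --------------------------------------------------------------------- IDX IO

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def _read_exact(f, nbytes, what):
    data = f.read(nbytes)
    if len(data) != nbytes:
        raise IdxFormatError(
            f"truncated {what} at byte offset {f.tell() - len(data)}: "
            f"wanted {nbytes} bytes, got {len(data)}"
        )
    return data


def load_idx(images_path, labels_path, invert: bool = False) -> GlyphCorpus:
    """Read an IDX image/label file pair into a corpus.

    Pixels are rescaled from 0..255 to [0, 1].  ``invert=True`` additionally
    flips polarity (real handwritten-digit archives store light ink on a dark
    background; this package works dark-on-light).  Writer identity is not
    represented in IDX, so all writer ids are the ``UNKNOWN_WRITER`` sentinel.
    """
    with open(images_path, "rb") as f:
        magic, n, rows, cols = struct.unpack(">IIII", _read_exact(f, 16, "image header"))
        if magic != _IDX_IMAGES_MAGIC:
            raise IdxFormatError(
                f"bad image magic number {magic:#010x} at byte offset 0"
            )
        raw = np.frombuffer(_read_exact(f, n * rows * cols, "image payload"), dtype=np.uint8)
        images = raw.reshape(n, rows, cols).astype(np.float32) / 255.0
    with open(labels_path, "rb") as f:
        magic, n_lab = struct.unpack(">II", _read_exact(f, 8, "label header"))
        if magic != _IDX_LABELS_MAGIC:
            raise IdxFormatError(
                f"bad label magic number {magic:#010x} at byte offset 0"
            )
        labels = np.frombuffer(_read_exact(f, n_lab, "label payload"), dtype=np.uint8)
    if n != n_lab:
        raise IdxFormatError(f"image/label record counts differ: {n} != {n_lab}")
    polarity = "light_on_dark"
    if invert:
        images = 1.0 - images
        polarity = "dark_on_light"
    writers = np.full(n, UNKNOWN_WRITER, dtype=np.int64)
    return GlyphCorpus(images, labels.astype(np.int64), writers, polarity)


def write_idx_images(images: np.ndarray, path) -> None:
    """Write an (n, rows, cols) float [0,1] array as an IDX ubyte image file."""
    n, rows, cols = images.shape
    with open(path, "wb") as f:
        f.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        f.write(np.rint(np.asarray(images) * 255.0).astype(np.uint8).tobytes())


def write_idx_labels(labels: np.ndarray, path) -> None:
    with open(path, "wb") as f:
        f.write(struct.pack(">II", _IDX_LABELS_MAGIC, len(labels)))
        f.write(np.asarray(labels).astype(np.uint8).tobytes())


def write_idx(corpus: GlyphCorpus, images_path, labels_path) -> None:
    """Write a corpus as an IDX image/label pair (inverse of ``load_idx``
    with ``invert=False``; pixel values are rounded back to 0..255)."""
    write_idx_images(corpus.images, images_path)
    write_idx_labels(corpus.labels, labels_path)
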