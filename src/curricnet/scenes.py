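"""Scene composition and task label encodings.

Stimuli are 84x84 images on a white (1.0) background with one or two 28x28
glyphs pasted at uniformly random, never-overlapping positions.  The padding
(rather than resizing) forces spatially invariant representations.  Three
label encodings are supported:

* ``single_digit``   one-hot over the 10 digit classes (the supporting task);
* ``parity_sum``     one-hot over {even, odd} of the two-digit sum --
  equivalently the XOR of the component parities, which makes the error
  signal orthogonal to the identity of any single digit;
* ``magnitude_sum``  a 20-unit binary magnitude code: unit i (1-based) is 1
  iff i <= X where X = d1 + d2.  This code is deliberately *not* orthogonal
  to the component digits.

Coordinates are 0-based (row, col); bounding boxes are half-open
(r0, c0, r1, c1).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations_with_replacement

import numpy as np

from .glyphgen import GlyphCorpus

CANVAS = 84
GLYPH = 28
MAX_POS = CANVAS - GLYPH  # inclusive upper bound for a corner coordinate

TASK_KINDS = ("single_digit", "parity_sum", "magnitude_sum")

PARITY_EVEN = 0  #: index of the "even" class in the parity one-hot
PARITY_ODD = 1

N_MAGNITUDE_UNITS = 20


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be found (unreachable in
    practice on an 84x84 canvas with two 28x28 glyphs)."""


@dataclasses.dataclass
class SceneDataset:
    """Composed task stimuli with labels and component-digit provenance.

    ``component_digits`` has shape (n, 2); the second entry is -1 for
    single-glyph scenes.  ``placements`` has shape (n, 2, 4) with -1 rows for
    absent glyphs.
    """

    images: np.ndarray
    task_kind: str
    labels: np.ndarray
    component_digits: np.ndarray
    placements: np.ndarray

    def __post_init__(self):
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        expected = {"single_digit": 10, "parity_sum": 2, "magnitude_sum": N_MAGNITUDE_UNITS}
        if self.labels.shape[1] != expected[self.task_kind]:
            raise ValueError(
                f"label width {self.labels.shape[1]} does not match "
                f"{self.task_kind} (want {expected[self.task_kind]})"
            )

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "SceneDataset":
        return SceneDataset(
            self.images[idx],
            self.task_kind,
            self.labels[idx],
            self.component_digits[idx],
            self.placements[idx],
        )


def enumerate_pair_classes():
    """All unordered digit pairs {d1, d2} with d1 <= d2 (55 classes)."""
    return list(combinations_with_replacement(range(10), 2))


def encode_parity(d1: int, d2: int) -> np.ndarray:
    """One-hot {even, odd} of d1 + d2."""
    _check_digit(d1), _check_digit(d2)
    out = np.zeros(2, dtype=np.float32)
    out[(d1 + d2) % 2] = 1.0  # PARITY_EVEN == 0, PARITY_ODD == 1
    return out


def encode_magnitude(d1: int, d2: int) -> np.ndarray:
    """20-unit magnitude code: unit i (1-based) is 1 iff i <= d1 + d2."""
    _check_digit(d1), _check_digit(d2)
    x = d1 + d2
    return (np.arange(1, N_MAGNITUDE_UNITS + 1) <= x).astype(np.float32)


def _check_digit(d):
    if not 0 <= int(d) <= 9:
        raise ValueError(f"digit out of range: {d}")


def _boxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def compose_scene(glyphs, seed, max_attempts: int = 1000):
    """Paste 1-2 glyphs onto a white 84x84 canvas at uniform positions.

    Glyph boxes always lie fully inside the canvas; for two glyphs the
    28x28 bounding boxes are kept disjoint by rejection sampling.  The paste
    operator is a pixel-wise minimum, so dark ink always wins over the white
    background and glyph pixels are preserved exactly.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 1 <= len(glyphs) <= 2:
        raise ValueError("compose_scene takes 1 or 2 glyphs")
    scene = np.ones((CANVAS, CANVAS), dtype=np.float32)
    boxes = []
    for g in glyphs:
        if g.shape != (GLYPH, GLYPH):
            raise ValueError(f"glyph must be {GLYPH}x{GLYPH}, got {g.shape}")
        for _ in range(max_attempts):
            r = int(rng.integers(0, MAX_POS + 1))
            c = int(rng.integers(0, MAX_POS + 1))
            box = (r, c, r + GLYPH, c + GLYPH)
            if all(not _boxes_overlap(box, other) for other in boxes):
                boxes.append(box)
                region = scene[r : r + GLYPH, c : c + GLYPH]
                np.minimum(region, g, out=region)
                break
        else:
            raise PlacementError(f"no non-overlapping position in {max_attempts} tries")
    return scene, boxes


class _ClassPool:
    """Shuffled per-class exemplar indices, consumed without replacement."""

    def __init__(self, corpus: GlyphCorpus, rng):
        self._idx = {}
        self._ptr = {}
        for d in range(10):
            idx = corpus.class_indices(d)
            self._idx[d] = idx[rng.permutation(len(idx))]
            self._ptr[d] = 0

    def take(self, digit: int) -> int:
        p = self._ptr[digit]
        if p >= len(self._idx[digit]):
            raise ValueError(
                f"exemplar pool for digit {digit} exhausted; "
                "n_scenes exceeds the without-replacement budget"
            )
        self._ptr[digit] = p + 1
        return int(self._idx[digit][p])


def build_task_dataset(
    corpus: GlyphCorpus, task_kind: str, n_scenes: int, seed: int
) -> SceneDataset:
    """Compose a labeled scene set from a glyph corpus.

    Single-digit scenes interleave the 10 classes round-robin.  Two-digit
    scenes cycle through random orderings of the 100 *ordered* digit pairs:
    within every block of 100 scenes each digit is equally represented, the
    odd- and even-sum classes are exactly balanced (so chance on the parity
    task is exactly 50%), and all 55 unordered pair classes appear.  Glyph
    exemplars are drawn without replacement until the per-class pools are
    exhausted.
    """
    if task_kind not in TASK_KINDS:
        raise ValueError(f"unknown task kind {task_kind!r}")
    if len(corpus) == 0 or n_scenes < 1:
        raise ValueError("corpus must be non-empty and n_scenes >= 1")
    n_glyphs = 1 if task_kind == "single_digit" else 2
    if n_scenes * n_glyphs > len(corpus):
        raise ValueError(
            f"{n_scenes} scenes need {n_scenes * n_glyphs} exemplars but the "
            f"corpus has {len(corpus)}"
        )
    rng = np.random.default_rng(seed)
    pool = _ClassPool(corpus, rng)

    images = np.empty((n_scenes, CANVAS, CANVAS), dtype=np.float32)
    component = np.full((n_scenes, 2), -1, dtype=np.int64)
    placements = np.full((n_scenes, 2, 4), -1, dtype=np.int64)
    label_rows = []

    if task_kind == "single_digit":
        digits_cycle = _balanced_cycle([(d,) for d in range(10)], n_scenes, rng)
    else:
        ordered_pairs = [(a, b) for a in range(10) for b in range(10)]
        digits_cycle = _balanced_cycle(ordered_pairs, n_scenes, rng)

    eye10 = np.eye(10, dtype=np.float32)
    for i, digits in enumerate(digits_cycle):
        glyph_idx = [pool.take(d) for d in digits]
        scene, boxes = compose_scene([corpus.images[g] for g in glyph_idx], rng)
        images[i] = scene
        component[i, : len(digits)] = digits
        placements[i, : len(digits)] = boxes
        if task_kind == "single_digit":
            label_rows.append(eye10[digits[0]])
        elif task_kind == "parity_sum":
            label_rows.append(encode_parity(*digits))
        else:
            label_rows.append(encode_magnitude(*digits))
    return SceneDataset(
        images, task_kind, np.asarray(label_rows, dtype=np.float32), component, placements
    )


def _balanced_cycle(classes, n, rng):
    """Yield n class tuples, cycling through fresh shuffles of ``classes``."""
    out = []
    while len(out) < n:
        order = rng.permutation(len(classes))
        out.extend(classes[k] for k in order)
    return out[:n]
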