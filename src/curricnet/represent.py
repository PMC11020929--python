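"""First-dense-layer representation analysis.

The 10-unit dense layer is where single-digit identity would be encoded if
the curriculum succeeds.  This module extracts its activations for a set of
diagnostic stimulus classes (by default the single digits 1, 3 and 8 and
their double-digit combinations -- 3 is visually similar to 8, 1 to
neither), embeds them in 2-D with t-SNE, and builds the per-class neuron
preference table.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations_with_replacement

import numpy as np

DEFAULT_DIAGNOSTIC_DIGITS = (1, 3, 8)


@dataclasses.dataclass
class ActivationMatrix:
    """Rows = stimuli, columns = the 10 first-dense-layer units."""

    values: np.ndarray
    class_labels: np.ndarray  # string label per row, e.g. "3" or "38"

    def __post_init__(self):
        if self.values.shape[1] != 10:
            raise ValueError("expected 10 first-dense-layer units")
        if len(self.values) != len(self.class_labels):
            raise ValueError("row/label mismatch")


def diagnostic_classes(digits=DEFAULT_DIAGNOSTIC_DIGITS):
    """Single digits plus all their unordered pair combinations."""
    singles = [(d,) for d in digits]
    pairs = list(combinations_with_replacement(sorted(digits), 2))
    return singles + pairs


def _scene_class(component_row) -> tuple:
    ds = tuple(int(d) for d in component_row if d >= 0)
    return tuple(sorted(ds))


def class_label(cls: tuple) -> str:
    return "".join(str(d) for d in cls)


def extract_activations(
    state,
    scenes,
    layer: str = "dense10",
    classes=None,
    n_per_class: int = 100,
) -> ActivationMatrix:
    """Forward-pass activations at ``layer`` for diagnostic stimuli.

    Takes up to ``n_per_class`` scenes of each diagnostic class from
    ``scenes`` (matched on component digits, order-insensitive).  Extraction
    is read-only: no gradients, no weight updates.
    """
    wanted = [tuple(sorted(c)) for c in (classes or diagnostic_classes())]
    rows, labels = [], []
    scene_cls = [_scene_class(c) for c in scenes.component_digits]
    for cls in wanted:
        idx = [i for i, sc in enumerate(scene_cls) if sc == cls][:n_per_class]
        if not idx:
            continue
        acts = state.activations(scenes.images[idx], layer)
        rows.append(acts.reshape(len(idx), -1))
        labels.extend([class_label(cls)] * len(idx))
    if not rows:
        raise ValueError("no scenes match the requested diagnostic classes")
    return ActivationMatrix(np.vstack(rows), np.asarray(labels))


def embed_2d(
    acts: ActivationMatrix,
    perplexity: float = 40.0,
    max_iter: int = 300,
    seed: int = 0,
    verbose: int = 0,
) -> np.ndarray:
    """t-SNE embedding of the activation rows into 2-D.

    The activations are fed to t-SNE directly, with no prior dimensionality
    reduction and random initialization.  Requires at least
    ``3 * perplexity`` rows for the neighborhoods to be meaningful.
    """
    from sklearn.manifold import TSNE

    n = len(acts.values)
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} rows is too few for perplexity {perplexity}; need >= {int(3 * perplexity)}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        init="random",
        random_state=seed,
        verbose=verbose,
    )
    return tsne.fit_transform(acts.values.astype(np.float64))


def neuron_preference_heatmap(state, scenes, classes=None, n_examples: int = 10):
    """Mean first-dense-layer activation per stimulus class, with units
    reordered by digit preference.

    A unit's preferred digit is the single-digit class maximizing its mean
    activation.  Units are assigned to digits greedily (digit 0 first, ties
    broken by unit index) so the returned permutation is a bijection and row
    k of the reordered table is the unit preferring digit k.

    Returns (table, permutation): ``table`` is a DataFrame whose rows are
    stimulus classes and whose columns are the reordered units; permutation
    maps new position -> original unit index.
    """
    import pandas as pd

    wanted = [tuple(sorted(c)) for c in (classes or [(d,) for d in range(10)])]
    scene_cls = [_scene_class(c) for c in scenes.component_digits]
    means = {}
    for cls in wanted:
        idx = [i for i, sc in enumerate(scene_cls) if sc == cls][:n_examples]
        if not idx:
            continue
        means[class_label(cls)] = state.activations(scenes.images[idx], "dense10").mean(axis=0)
    if not means:
        raise ValueError("no scenes match the requested classes")
    table = pd.DataFrame(means).T

    single_rows = [class_label((d,)) for d in range(10) if class_label((d,)) in table.index]
    pref_source = table.loc[single_rows] if single_rows else table
    permutation = _greedy_unit_assignment(pref_source.to_numpy())
    table = table.iloc[:, permutation]
    table.columns = [f"unit{u}" for u in permutation]
    return table, permutation


def _greedy_unit_assignment(class_by_unit: np.ndarray) -> list:
    """Assign one unit per class: classes in order, each takes its
    highest-activation unassigned unit (ties to the lowest unit index)."""
    n_classes, n_units = class_by_unit.shape
    free = list(range(n_units))
    perm = []
    for c in range(min(n_classes, n_units)):
        best = max(free, key=lambda u: (class_by_unit[c, u], -u))
        perm.append(best)
        free.remove(best)
    perm.extend(free)
    return perm
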