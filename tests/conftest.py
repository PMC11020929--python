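"""Shared fixtures: small corpora and scene sets reused across test modules.

Everything is generated programmatically; fixtures are session-scoped where
the contents are immutable.
"""

import numpy as np
import pytest

from curricnet import ModelSpec, build_network, build_task_dataset, make_glyph_corpus, split_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """600 glyphs, 5 writers - enough structure for scene/schedule tests."""
    return make_glyph_corpus(n_per_class=60, n_writers=5, seed=11)


@pytest.fixture(scope="session")
def corpus_split(tiny_corpus):
    return split_corpus(tiny_corpus, holdout_fraction=0.25, seed=3)


@pytest.fixture(scope="session")
def parity_scenes(corpus_split):
    train, _ = corpus_split
    return build_task_dataset(train, "parity_sum", 200, seed=5)


@pytest.fixture(scope="session")
def single_scenes(corpus_split):
    train, _ = corpus_split
    return build_task_dataset(train, "single_digit", 200, seed=6)


@pytest.fixture(scope="session")
def magnitude_scenes(corpus_split):
    train, _ = corpus_split
    return build_task_dataset(train, "magnitude_sum", 100, seed=7)


@pytest.fixture(scope="session")
def fresh_state():
    """Untrained two-conv network (shared read-only)."""
    return build_network(ModelSpec(), seed=42)


@pytest.fixture(scope="session")
def magnitude_state():
    return build_network(ModelSpec(task2="magnitude_sum"), seed=42)
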