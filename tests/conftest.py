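import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default_deterministic", derandomize=True, deadline=None)
settings.load_profile("default_deterministic")

from chinpaint import (
    LabeledImageSet,
    build_classifier,
    make_cross_line,
    make_glyph_dataset,
    train,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def crossline():
    """Clean cross-line image and its damaged copy (50x50, grey band)."""
    return make_cross_line()


@pytest.fixture(scope="session")
def glyph_split():
    """Small glyph dataset split 80/20 into train and test sets."""
    images, labels = make_glyph_dataset(20, 7)
    order = np.random.default_rng(7).permutation(len(images))
    test_idx, train_idx = order[:40], order[40:]
    return (
        LabeledImageSet(images[train_idx], labels[train_idx], source="glyphs"),
        LabeledImageSet(images[test_idx], labels[test_idx], source="glyphs"),
    )


@pytest.fixture(scope="session")
def trained_model(glyph_split):
    train_set, _ = glyph_split
    return train(build_classifier(7), train_set, epochs=10, seed=7)
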