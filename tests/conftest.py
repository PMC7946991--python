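import numpy as np
import pytest

from pannetrisk import synthgen
from pannetrisk.met_classifier import MetScoreMap


@pytest.fixture(scope="session")
def textures():
    return synthgen.DEFAULT_TEXTURES


@pytest.fixture(scope="session")
def small_slide():
    """An 8×8-tile mosaic at 32 px tiles with its annotations and layout."""
    return synthgen.make_synthetic_slide(layout_seed=11, grid=(8, 8), tile_px=32)


def random_score_map(rng: np.random.Generator, rows=30, cols=30, compartment="CANCER"):
    """A random valid MetScoreMap for oracle-equivalence testing."""
    scores = rng.beta(0.6, 1.2, size=(rows, cols))
    mask = rng.random((rows, cols)) < 0.8
    scores = np.where(mask, scores, 0.0)
    return MetScoreMap(
        scores=scores, valid_mask=mask, compartment=compartment, slide_id="rand"
    )


@pytest.fixture(scope="session")
def labeled_texture_tiles(textures):
    """200 tiles/class at 32 px for classifier training tests."""
    rng = np.random.default_rng(1234)
    tiles, labels = [], []
    for cls, params in textures.items():
        for _ in range(200):
            tiles.append(
                synthgen.make_texture_tile(params, size=32, seed=int(rng.integers(2**31 - 1)))
            )
            labels.append(cls)
    return tiles, labels
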