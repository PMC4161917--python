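import warnings

import numpy as np
import pytest

import hahsearch as hs
from hahsearch.search import SearchConfig

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_smear():
    """A compact smear field with 5 same-class cells for pipeline tests."""
    cfg = hs.FixtureConfig(
        height=600, width=600, n_objects=7,
        class_mix={"neutrophil": 5 / 7, "lymphocyte": 2 / 7},
        distractor_count=860, seed=3,
    )
    return hs.make_smear_fixture(cfg)


@pytest.fixture(scope="session")
def default_search_config():
    return SearchConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_two_tone_patch(rng, size=24, colors=None):
    """A structured two-color patch: left half one color, right the other."""
    if colors is None:
        colors = rng.integers(0, 256, size=(2, 3))
    patch = np.empty((size, size, 3), dtype=np.uint8)
    patch[:, : size // 2] = colors[0]
    patch[:, size // 2 :] = colors[1]
    return patch
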