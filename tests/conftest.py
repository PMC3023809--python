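import numpy as np
import pytest

from atlaskit import synthetic_fixtures as sf


@pytest.fixture
def spec():
    return sf.FixtureSpec(seed=7, volume_shape=(16, 16, 16), n_structures=7,
                          hierarchy_depth=3)


@pytest.fixture
def atlas(spec):
    """A small two-layer synthetic atlas (anatomic + functional contexts)."""
    return sf.make_atlas(spec)


@pytest.fixture
def labelset(spec):
    return sf.make_label_tree(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
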