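import numpy as np
import pytest

from fscchange.pipeline import FeatureConfig, build_feature_table
from fscchange.synthetic import SceneConfig, generate_scene_pair


@pytest.fixture(scope="session")
def scene_pair():
    """A small two-epoch scene with 150 FSCs and 8% injected changes."""
    cfg = SceneConfig(grid_shape=(128, 128), n_fsc=150, change_fraction=0.08, seed=5)
    s1, s2, records = generate_scene_pair(cfg)
    return cfg, s1, s2, records


@pytest.fixture(scope="session")
def feature_table(scene_pair):
    """Epoch-1 feature table of the small scene."""
    _, s1, _, records = scene_pair
    return build_feature_table(s1, records, FeatureConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
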