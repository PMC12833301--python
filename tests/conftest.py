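import numpy as np
import pytest

from mgtcn.features import FeatureConfig, build_feature_table
from mgtcn.preprocess import PreprocConfig, preprocess_pipeline
from mgtcn.synthetic import SynthConfig, generate_recordings


@pytest.fixture(scope="session")
def small_rec():
    """30 trials, 8 channels, 8 s @ 200 Hz — fast shared raw dataset."""
    cfg = SynthConfig(n_subjects=1, n_trials_per_class=10, n_channels=8, trial_len=8.0, seed=11)
    return generate_recordings(cfg)


@pytest.fixture(scope="session")
def small_features(small_rec):
    """Raw (pre-PCA) feature table for the small dataset: 30 x 56."""
    segs = preprocess_pipeline(small_rec, PreprocConfig())
    return build_feature_table(segs, FeatureConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
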