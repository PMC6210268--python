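import numpy as np
import pytest

import grazeclass as gc


@pytest.fixture(scope="session")
def small_trial():
    """600 s default-regime collar trial, seed 1 (9600 samples, ~170 windows)."""
    cfg = gc.TrialConfig(duration_s=600.0, seed=1)
    stream, track = gc.generate_trial(cfg)
    return cfg, stream, track


@pytest.fixture(scope="session")
def small_windows(small_trial):
    _, stream, track = small_trial
    return gc.discretise(gc.build_channels(stream), track)


@pytest.fixture(scope="session")
def small_features(small_windows):
    df = gc.extract_feature_matrix(small_windows)
    X = df.drop(columns=["label", "is_mixed"])
    return X, df["label"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
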