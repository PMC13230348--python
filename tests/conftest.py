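import numpy as np
import pytest

from synthmetrics import FeatureMatrix, ScenarioSpec, gen_feature_clouds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_pair(rng):
    """Two independent feature clouds from the same standard Gaussian."""
    x = FeatureMatrix(rng.standard_normal((60, 4)), source="real")
    y = FeatureMatrix(rng.standard_normal((60, 4)), source="synthetic")
    return x, y


@pytest.fixture
def two_mode_clouds():
    """Well-separated two-mode scenario, no pathology, fixed seed."""
    return gen_feature_clouds(ScenarioSpec(n_real=200, n_synth=200, seed=7))
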