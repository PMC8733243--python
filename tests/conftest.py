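import numpy as np
import pytest

from hdnn import FeatureTable, SyntheticConfig, generate_feature_table


@pytest.fixture
def tiny_table() -> FeatureTable:
    """4 samples x 2 features, both classes present."""
    return FeatureTable(
        features=np.array([[0.0, 1.0], [1.5, -2.0], [3.25, 0.5], [-1.0, 4.0]]),
        labels=np.array([0, 1, 0, 1]),
        feature_names=["f1", "f2"],
        sample_ids=["a", "b", "c", "d"],
    )


@pytest.fixture
def imbalanced_table() -> FeatureTable:
    """100 samples (10+/90-) of seeded noise, for split/subsample tests."""
    rng = np.random.default_rng(42)
    labels = np.array([1] * 10 + [0] * 90)
    return FeatureTable(
        features=rng.normal(size=(100, 3)),
        labels=labels,
        feature_names=["f1", "f2", "f3"],
        sample_ids=[f"s{i}" for i in range(100)],
    )


@pytest.fixture
def blob_table() -> FeatureTable:
    """Two well-separated Gaussian blobs (6 SD), 29 features, balanced n=500."""
    return generate_feature_table(
        SyntheticConfig(
            n_positive=250, n_negative=250, effect_size=6.0, n_informative=10, seed=11
        )
    )
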