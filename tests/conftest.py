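import numpy as np
import pytest

from mantisfs import (
    FeatureTable,
    FitnessSpec,
    SyntheticFeatureSpec,
    gen_feature_table,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """200x64 table with 8 planted informative columns (effect 2.0)."""
    table, planted = gen_feature_table(
        SyntheticFeatureSpec(
            n_samples=200, n_features=64, n_informative=8, effect_size=2.0, seed=11
        )
    )
    return table, planted


@pytest.fixture(scope="session")
def knn_spec():
    return FitnessSpec(classifier="KNN", n_folds=5, alpha=0.01, seed=0)


@pytest.fixture()
def two_feature_table():
    """One perfectly separating feature, one pure noise feature."""
    rng = np.random.default_rng(7)
    n = 40
    labels = np.array([0, 1] * (n // 2))
    sep = labels * 10.0 + rng.normal(0, 0.1, n)
    noise = rng.normal(0, 1.0, n)
    return FeatureTable(
        values=np.column_stack([noise, sep]),
        labels=labels,
        feature_ids=np.array(["noise", "separating"]),
        sample_ids=np.array([f"s{i}" for i in range(n)]),
    )
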