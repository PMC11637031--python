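import numpy as np
import pytest

from msfs.synthetic_data import TableSpec, make_feature_table


@pytest.fixture(scope="session")
def random_images_8x8():
    """20 seeded random 8x8 gray images on 8 levels (keeps brute-force
    GLCM oracles cheap while exercising every orientation)."""
    rng = np.random.default_rng(2024)
    return [rng.integers(0, 8, size=(8, 8)) for _ in range(20)]


@pytest.fixture(scope="session")
def planted_table():
    """Default-condition planted-feature table: 150/class, D=50, 5
    informative columns at effect size 1.5."""
    df, informative = make_feature_table(TableSpec(seed=42))
    return df, informative


@pytest.fixture(scope="session")
def small_table():
    """Cheap table for smoke runs: 30/class, D=12, 3 informative."""
    df, informative = make_feature_table(
        TableSpec(n_per_class=30, n_features=12, n_informative=3, seed=7)
    )
    return df, informative
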