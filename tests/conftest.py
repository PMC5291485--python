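import numpy as np
import pytest

from gliotex import FeatureTable, extract_table, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """30 LGG-like + 20 GBM-like phantoms at full separability."""
    images, labels = generate_cohort(30, 20, separability=1.0, seed=7)
    return images, labels


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    images, labels = small_cohort
    df = extract_table(images, labels=labels)
    return FeatureTable.from_dataframe(df)


def random_glcm(rng, G, sparse=False):
    """A random valid (symmetric, normalized) GLCM."""
    a = rng.random((G, G))
    if sparse:
        a *= rng.random((G, G)) < 0.3
        if a.sum() == 0:
            a[0, 0] = 1.0
    a = a + a.T
    return a / a.sum()
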