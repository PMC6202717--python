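import numpy as np
import pytest

from ddetect import prepare_census, select_null_bandwidth


@pytest.fixture(scope="session")
def two_cluster_census():
    """30 entities in two log-mass clusters separated by ~2 log10 units."""
    rng = np.random.default_rng(42)
    masses = np.concatenate(
        [10 ** rng.normal(1.0, 0.15, 15), 10 ** rng.normal(3.0, 0.15, 15)]
    )
    return prepare_census(masses)


@pytest.fixture(scope="session")
def unimodal_census():
    """30 entities from a single log-normal mode."""
    rng = np.random.default_rng(7)
    return prepare_census(10 ** rng.normal(2.0, 0.3, 30))


@pytest.fixture(scope="session")
def unimodal_null(unimodal_census):
    return select_null_bandwidth(unimodal_census)
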