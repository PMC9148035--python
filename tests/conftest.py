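import numpy as np
import pytest

from nutripatterns import SyntheticConfig, generate_cohort
from nutripatterns.synthetic import DEFAULT_CENTROIDS, DEFAULT_LOADINGS


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped cohort: 608 participants, six clusters."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def block_loadings():
    """Clean two-factor block structure: nine variables at 0.8 per factor."""
    L = np.zeros((18, 2))
    L[:9, 0] = 0.8
    L[9:, 1] = 0.8
    return L


@pytest.fixture(scope="session")
def planted_cohort(block_loadings):
    """Single-population cohort (n=2000) with the clean block loadings."""
    cfg = SyntheticConfig(
        n_per_cluster=(2000,),
        centroids=np.zeros((1, 2)),
        loadings_true=block_loadings,
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def separated_cohort():
    """Six well-separated planted centroids, study-sized (n=608)."""
    cfg = SyntheticConfig(centroids=DEFAULT_CENTROIDS * 3.0, seed=13)
    return generate_cohort(cfg)
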