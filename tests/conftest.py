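import numpy as np
import pandas as pd
import pytest

from metatrait.synthetic import (
    AxisSpec,
    ClassicalSpec,
    ClusterSpec,
    SyntheticConfig,
    gen_study,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A miniature study: 240 metabolites x 40 species, defaults otherwise."""
    return SyntheticConfig(
        n_metabolites=240,
        n_species=40,
        classical=ClassicalSpec(n_genera=10, species_per_genus=4),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return gen_study(small_config, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size study bundle (300 species x 3000 metabolites), shared."""
    return gen_study(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_traits():
    """Complete 6-species x 3-trait table with simple numbers."""
    return pd.DataFrame(
        {
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "b": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
            "c": [0.5, 0.7, 0.2, 0.9, 0.4, 0.8],
        },
        index=[f"sp{i}" for i in range(6)],
    )
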