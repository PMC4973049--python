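import numpy as np
import pytest

from poisonprev import psa
from poisonprev.params import load_config, sample_parameters, settings_from_config


@pytest.fixture(scope="session")
def medicinal_config():
    return load_config("medicinal")


@pytest.fixture(scope="session")
def nonmedicinal_config():
    return load_config("nonmedicinal")


@pytest.fixture(scope="session")
def medicinal_settings(medicinal_config):
    return settings_from_config(medicinal_config)


@pytest.fixture(scope="session")
def medicinal_point_draw(medicinal_config):
    """Point-estimate parameter set (scalar-shaped)."""
    return sample_parameters(medicinal_config, np.random.default_rng(0),
                             point_estimate=True)


@pytest.fixture(scope="session")
def medicinal_psa():
    """Base-case medicinal PSA at the published 4,000 draws (shared across
    tests; ~0.2 s)."""
    return psa.run_variant("medicinal", n_draws=4000, seed=1)


@pytest.fixture(scope="session")
def nonmedicinal_psa():
    return psa.run_variant("nonmedicinal", n_draws=4000, seed=1)
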