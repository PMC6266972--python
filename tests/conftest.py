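import numpy as np
import pytest

import tritrace as tt
from tritrace.growth import TABLE_GROWTH_DEFAULTS
from tritrace.synthetic import (
    SyntheticFieldSpec,
    generate_measurements,
    generate_soil_field,
)


@pytest.fixture(scope="session")
def setup():
    """Placeholder default parameterisation."""
    return tt.default_setup()


@pytest.fixture(scope="session")
def growth_defaults():
    return dict(TABLE_GROWTH_DEFAULTS)


@pytest.fixture(scope="session")
def survey(setup):
    """52-site synthetic survey, 32 mature, noisy measurements (frozen seeds)."""
    spec = SyntheticFieldSpec(seed=2025)
    table = generate_soil_field(spec)
    return generate_measurements(table, setup, noise_cv=0.3, seed=2026)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
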