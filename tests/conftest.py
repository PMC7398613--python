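import numpy as np
import pytest

from adherepath import fixtures
from adherepath.synth import SyntheticCohortConfig, calibrate, generate_cohort


@pytest.fixture(scope="session")
def hird_raw():
    """The packaged cohort SSD exactly as printed (asymmetric PCP row)."""
    return fixtures.hird_ssd(symmetrized=False)


@pytest.fixture(scope="session")
def hird():
    """The symmetrized cohort SSD used for model fitting."""
    return fixtures.hird_ssd(symmetrized=True)


@pytest.fixture(scope="session")
def laterals():
    return fixtures.trustr_laterals()


@pytest.fixture(scope="session")
def default_config(hird):
    return SyntheticCohortConfig(target=hird, medians=fixtures.hird_medians())


@pytest.fixture(scope="session")
def calibration(default_config):
    """Marginal + latent calibration (one ~20 s solve shared by the session)."""
    return calibrate(default_config)


@pytest.fixture(scope="session")
def default_cohort(default_config, calibration):
    """Full-size synthetic cohort plus its moment-recovery report."""
    return generate_cohort(default_config, calibration=calibration)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
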