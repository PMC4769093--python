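import pytest

from oligoscreen import AssignmentConfig, ClassifierConfig
from oligoscreen.synth import abeta40_scenario, default_calibration


@pytest.fixture
def calibration():
    return default_calibration()


@pytest.fixture
def scenario():
    """Noiseless amyloid-beta(1-40) scenario with planted linear growth."""
    return abeta40_scenario(seed=0, noise_cv=0.0)


@pytest.fixture
def assignment_config():
    return AssignmentConfig()


@pytest.fixture
def classifier_config():
    return ClassifierConfig()
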