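import pytest

from emotrace.cohort import generate_cohort
from emotrace.pipeline import calibration_config, extract_features


@pytest.fixture(scope="session")
def calib_config():
    """Scaled-down study configuration with the default planted effects."""
    return calibration_config(null=False)


@pytest.fixture(scope="session")
def small_cohort(calib_config):
    return generate_cohort(7, calib_config.cohort)


@pytest.fixture(scope="session")
def small_features(small_cohort, calib_config):
    return extract_features(small_cohort, calib_config)
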