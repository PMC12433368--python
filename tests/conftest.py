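import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from hbscreen import (
    PeakMeasurement,
    SampleRecord,
    default_p_alpha,
    default_p_beta,
    load_is_config,
    load_transition_registry,
)


@pytest.fixture(scope="session")
def is_config():
    return load_is_config()


@pytest.fixture(scope="session")
def registry():
    return load_transition_registry()


@pytest.fixture(scope="session")
def p_alpha_model():
    return default_p_alpha()


@pytest.fixture(scope="session")
def p_beta_model():
    return default_p_beta()


def make_sample(sample_id="S1", areas=None, is_areas=None, noises=None):
    """Build a core-panel sample; by default every area equals its IS area."""
    panel = ("alphaT1", "alphaT3", "betaT1", "betaT2", "gammaT10", "deltaT2", "zetaT8")
    areas = areas or {}
    is_areas = is_areas or {}
    noises = noises or {}
    measurements = [
        PeakMeasurement(sample_id, pid, areas.get(pid, 500.0),
                        is_areas.get(pid, 500.0), noises.get(pid))
        for pid in panel
    ]
    return SampleRecord(sample_id=sample_id, age_days=5, measurements=measurements)
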