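"""Shared fixtures: simulator configurations and seeded end-to-end tables.

The heavier end-to-end artefacts (10-subject fitting and clogging feature
tables at simulator defaults) are session-scoped so the evaluation tests and
the acceptance suite reuse one simulation each.
"""

import numpy as np
import pytest

from respira import (
    SimConfig,
    SubjectPanel,
    extract_feature_table,
    simulate_protocol,
)


@pytest.fixture
def noise_free_cfg() -> SimConfig:
    return SimConfig(noise_sd_frac=0.0, drift_sd_frac=0.0, rate_jitter_frac=0.0)


@pytest.fixture
def default_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def fitting_recordings():
    """Ten-subject fitted→loose→fitted protocol at simulator defaults."""
    return simulate_protocol("fitting", SubjectPanel(), SimConfig(), seed=1)


@pytest.fixture(scope="session")
def fitting_table(fitting_recordings):
    return extract_feature_table([pr.recording for pr in fitting_recordings])


@pytest.fixture(scope="session")
def clogging_recordings():
    """Ten-subject six-level clogging protocol at simulator defaults."""
    return simulate_protocol("clogging", SubjectPanel(), SimConfig(), seed=1)


@pytest.fixture(scope="session")
def clogging_table(clogging_recordings):
    return extract_feature_table([pr.recording for pr in clogging_recordings])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
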