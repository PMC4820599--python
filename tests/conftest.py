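"""Shared fixtures: small geometries and the scaled-down Monte-Carlo study."""

import numpy as np
import pytest

from megcoh.geometry import (
    build_sensor_cap,
    build_wrinkled_source_space,
    compute_lead_field,
    normalize_lead_field,
)
from megcoh.pipeline import StudyConfig, run_study

# fixed seed for every test-local RNG; independent of the acceptance script
TEST_SEED = 101


@pytest.fixture(scope="session")
def small_geometry():
    """162-vertex wrinkled source space with a 60-sensor cap and lead field."""
    ss = build_wrinkled_source_space(2, 0.08, 0.1)
    sa = build_sensor_cap(60, 0.12, 0.75, conductor_radius=0.09)
    lf = normalize_lead_field(compute_lead_field(ss, sa, conductor_radius=0.09))
    return ss, sa, lf


@pytest.fixture(scope="session")
def scaled_study_config():
    """The scaled-down study design: 50 location pairs, point/2/4 cm² sources,
    couplings 0.2/0.4, SNR 0/−20 dB, 7-decade regularization grid."""
    return StudyConfig(
        n_location_pairs=50,
        patch_areas=(0.0, 2.0, 4.0),
        couplings=(0.2, 0.4),
        snr_levels=(0.0, -20.0),
        master_seed=TEST_SEED,
    )


@pytest.fixture(scope="session")
def scaled_study(scaled_study_config):
    """Full scaled-down Monte-Carlo run (600 cells); shared across tests."""
    result = run_study(scaled_study_config)
    assert not result.failures, f"study cells failed: {result.failures[:3]}"
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)
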