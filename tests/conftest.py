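import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles / edf_writer helpers

from eegsex import (
    CohortConfig,
    EntropyConfig,
    Recording,
    cohort_epochs,
    extract_features,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg() -> CohortConfig:
    """Miniature cohort: 2M/2F subjects, 3 channels, 20 s at 250 Hz."""
    return CohortConfig.fixture(seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_cohort):
    return cohort_epochs(tiny_cohort, retain_s=None)


@pytest.fixture(scope="session")
def tiny_features(tiny_epochs):
    """Unnormalised feature matrix over all four measures (80 x 12)."""
    return extract_features(tiny_epochs, EntropyConfig())


@pytest.fixture
def two_channel_recording(rng) -> Recording:
    return Recording(
        subject_id="S01",
        sex="male",
        fs=1000.0,
        channels=["Fp1", "Fp2"],
        data=rng.standard_normal((2, 4000)),
    )
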