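import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gradientflow import Parcellation, SynthParams, simulate_cohort

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def tiny_parcellation() -> Parcellation:
    return Parcellation(
        roi_ids=("r0", "r1", "r2"),
        network_labels=("DMN", "SMC", "VIS"),
        voxel_counts=(10, 20, 30),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 42-ROI, 2+2-subject cohort reused across read-only tests."""
    params = SynthParams(n_roi=42, n_subjects_per_group=(2, 2), seed=7)
    return simulate_cohort(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
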