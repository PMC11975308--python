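import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from progrisk import cohort_prep as cp
from progrisk.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject feature-payload cohort shared across tests."""
    return simulate_cohort(SimConfig(n_subjects=120, seed=11))


@pytest.fixture(scope="session")
def matched_ids(small_cohort):
    match = cp.match_case_control(small_cohort.manifest)
    return sorted({s for pair in match.pairs for s in pair})


@pytest.fixture(scope="session")
def pairs_h2(small_cohort, matched_ids):
    return cp.build_pairs(small_cohort.manifest, [2.0], matched_ids)[2.0]
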