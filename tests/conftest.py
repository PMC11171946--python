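import numpy as np
import pytest

from dynaperv import CohortParams, simulate_cohort

# Per-category (ncct, cta, ctv) HU column means of the clinical summary table;
# used across modules as canonical representatives of each pattern.
GROUP_MEAN_TRIPLETS = {
    "C_NE": (68.6, 67.0, 68.7),
    "C_NW": (62.5, 73.1, 78.2),
    "C_W": (61.3, 95.3, 68.5),
    "C_LE": (62.5, 61.4, 79.8),
}


@pytest.fixture(scope="session")
def default_params() -> CohortParams:
    return CohortParams()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return simulate_cohort(default_params, seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
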