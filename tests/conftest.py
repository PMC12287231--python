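import numpy as np
import pytest

from sirsurv import SimulationConfig, add_biomarkers, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject default-mode cohort with biomarker columns."""
    cfg = SimulationConfig(seed=424242, n_subjects=300)
    return add_biomarkers(simulate_cohort(cfg))


@pytest.fixture(scope="session")
def medium_cohort():
    """1000-subject default-mode cohort with biomarker columns."""
    cfg = SimulationConfig(seed=171717, n_subjects=1000)
    return add_biomarkers(simulate_cohort(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
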