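import numpy as np
import pytest

import longmed as lm

# single base seed for every stochastic fixture in the suite
BASE_SEED = 20_260_919


@pytest.fixture(scope="session")
def default_panel() -> lm.CohortPanel:
    """One default synthetic cohort (n=337, 9 visits)."""
    return lm.simulate_cohort(lm.DGPConfig(seed=BASE_SEED))


@pytest.fixture(scope="session")
def small_panel() -> lm.CohortPanel:
    """A cheap 60-subject cohort for plumbing tests."""
    return lm.simulate_cohort(lm.DGPConfig(n_subjects=60, seed=BASE_SEED + 1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(BASE_SEED)
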