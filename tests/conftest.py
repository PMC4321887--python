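import numpy as np
import pytest

from prfcohort import (
    CohortConfig,
    PRFFitter,
    generate_cohort,
    make_bar_stimulus,
)


@pytest.fixture(scope="session")
def stim():
    return make_bar_stimulus()


@pytest.fixture(scope="session")
def fitter(stim):
    """Shared grid-stage precompute (a few seconds, reused everywhere)."""
    return PRFFitter(stim)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for structural tests (8 participants, V1+V2)."""
    return generate_cohort(
        CohortConfig(n_participants=8, n_vertices=400, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
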