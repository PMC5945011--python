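from __future__ import annotations

import numpy as np
import pytest

from racestop.design import build_design, default_assignments
from racestop.preprocess import classify_trials
from racestop.stimuli import bundled_stimuli, stimulus_lookup
from racestop.synthetic_data import default_parameters, simulate_cohort


@pytest.fixture(scope="session")
def stimuli():
    return bundled_stimuli()


@pytest.fixture(scope="session")
def lookup(stimuli):
    return stimulus_lookup(stimuli)


@pytest.fixture(scope="session")
def assignments(stimuli):
    return default_assignments(stimuli, seed=1)


@pytest.fixture(scope="session")
def schedule(stimuli, assignments):
    return build_design(stimuli, assignments[0], seed=1)


@pytest.fixture(scope="session")
def default_params():
    params, shifts = default_parameters()
    return params, shifts


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated participants, classified (shared across tests for speed)."""
    return classify_trials(simulate_cohort(6, seed=2024))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
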