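import numpy as np
import pytest

from afprog import baseline_parameters, run_ensemble, simulate_patient
from afprog.cli import make_fixture


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def telegraph():
    """Constant-rate limit: A(t) = 4/yr, R(t) = 20/yr for all t."""
    return make_fixture("constant_rate")


@pytest.fixture(scope="session")
def toy_trajectory():
    """Three hand-written episodes exercising all three stage rules."""
    return make_fixture("toy_episodes")


@pytest.fixture(scope="session")
def baseline_trajectories(baseline):
    """100 full-lifetime baseline trajectories (shared across tests)."""
    seeds = np.random.SeedSequence(2024).spawn(100)
    return [simulate_patient(baseline, s) for s in seeds]


@pytest.fixture(scope="session")
def baseline_ensemble(baseline):
    """Desk-scale baseline ensemble: 500 patients, birth to age 100."""
    return run_ensemble(baseline, n=500, master_seed=11)
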