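import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from startrack.randomization import generate_schedule
from startrack.synthetic_data import (
    SimulationConfig,
    simulate_retest_study,
    simulate_validity_study,
)


def make_validity_trials(seed=0, n_subjects=20, **overrides):
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed, **overrides)
    schedule = generate_schedule(n_subjects, seed)
    return simulate_validity_study(cfg, schedule)


def make_retest_trials(seed=0, n_subjects=11, **overrides):
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed, **overrides)
    return simulate_retest_study(cfg)


@pytest.fixture
def validity_trials():
    return make_validity_trials(seed=42)


@pytest.fixture
def retest_trials():
    return make_retest_trials(seed=42)
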