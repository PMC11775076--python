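import pytest

import ccaf


@pytest.fixture(scope="session")
def schedule32():
    """Reference-scale schedule: 32 trials per level, 96 total."""
    return ccaf.generate_schedule(32, seed=0)


@pytest.fixture(scope="session")
def cohort_summary(schedule32):
    """One simulated default cohort aggregated to subject x level counts."""
    profiles = ccaf.generate_cohort(ccaf.CohortConfig(seed=7))
    trials = ccaf.simulate_cohort_trials(profiles, schedule32, seed=11)
    return ccaf.aggregate(trials)
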