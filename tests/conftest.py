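import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import accelrel as ar


@pytest.fixture(scope="session")
def small_config():
    return ar.SimulationConfig(n_subjects=5, n_days=21, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A 5-subject x 21-day cohort: epoch series, truth and the day table."""
    series, truth = ar.simulate_cohort(small_config)
    table, _ = ar.simulate_day_table(small_config)
    return series, truth, table


@pytest.fixture(scope="session")
def reduced_days(small_cohort):
    series, _, _ = small_cohort
    minutes = ar.detect_nonwear(ar.cohort_to_minutes(series))
    return ar.summarize_days(minutes)


@pytest.fixture(scope="session")
def study_day_table():
    """Day-level table at the reference design scale (87 x 21)."""
    table, truth = ar.simulate_day_table(ar.SimulationConfig(seed=11))
    return table, truth
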