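import warnings

import numpy as np
import pytest

from ergofield import (
    CohortSpec,
    ShiftSchedule,
    bandpass,
    default_ground_truth,
    simulate_cohort,
    simulate_emg,
    window_features,
)


@pytest.fixture(scope="session")
def smoke_schedule() -> ShiftSchedule:
    return ShiftSchedule.smoke()


@pytest.fixture(scope="session")
def standard_schedule() -> ShiftSchedule:
    return ShiftSchedule.standard()


@pytest.fixture(scope="session")
def small_roster():
    return simulate_cohort(CohortSpec(n_per_group=2, seed=11))


@pytest.fixture(scope="session")
def small_truth(small_roster):
    return default_ground_truth(small_roster, seed=11)


@pytest.fixture(scope="session")
def smoke_emg_features(small_roster, small_truth, smoke_schedule):
    """Windowed features of one clean bandpassed smoke-shift recording."""
    rec = simulate_emg("S01", "left", smoke_schedule, small_truth, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return window_features(bandpass(rec), smoke_schedule)


@pytest.fixture(scope="session")
def long_schedule() -> ShiftSchedule:
    """A 3.5-h shift with a 20-min break: 20 analysis windows, 18 in work."""
    return ShiftSchedule.from_times("7:30", "11:00", "9:00", break_minutes=20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
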