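import numpy as np
import pytest

from dsrbd_dynamics.io import (DelaySchedule, SpectrometerContext,
                               read_delay_schedule)

#: printed acquisition schedules (ms, '*' = duplicate)
R1_SCHEDULE_TEXT = "10, 30*, 50, 100, 200, 300, 450*, 600"
R2_SCHEDULE_TEXT = "17, 34*, 51, 68, 85, 102, 136*, 170"
NU_CPMG_HZ = [25.0, 50.0, 75.0, 125.0, 175.0, 275.0, 375.0, 525.0,
              675.0, 825.0, 1000.0]


@pytest.fixture
def r1_schedule() -> DelaySchedule:
    return read_delay_schedule(R1_SCHEDULE_TEXT)


@pytest.fixture
def r2_schedule() -> DelaySchedule:
    return read_delay_schedule(R2_SCHEDULE_TEXT)


@pytest.fixture
def ctx600() -> SpectrometerContext:
    return SpectrometerContext(600.0)


@pytest.fixture
def ctx800() -> SpectrometerContext:
    return SpectrometerContext(800.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240808)
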