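import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from flysomnus import ActivityTrace, LightSchedule

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # make_trace is a stateless factory, safe to share across examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

#: lights-on instant of the default schedule, used as a canonical ZT0 start
START_ZT0 = pd.Timestamp("2024-01-01 08:00")


@pytest.fixture
def ld_schedule() -> LightSchedule:
    return LightSchedule()


@pytest.fixture
def make_trace(ld_schedule):
    """Factory for minute-binned traces starting at ZT0."""

    def _make(counts, start=START_ZT0, schedule=ld_schedule, **kw):
        defaults = dict(fly_id="f1", genotype="g", sex="M", bin_min=1)
        defaults.update(kw)
        return ActivityTrace(
            start=start, counts=np.asarray(counts), schedule=schedule, **defaults
        )

    return _make


@pytest.fixture
def dd_schedule():
    """Two LD days, then constant darkness from lights-off of day 1."""
    return LightSchedule(
        regime="DD", dd_start=START_ZT0 + pd.Timedelta(minutes=1440 + 720)
    )
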