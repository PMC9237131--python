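import numpy as np
import pandas as pd
import pytest

from glyforecast.datatypes import CgmSeries, EventLog, SubjectParams, regular_grid
from glyforecast.simulate import generate_cohort, synthesize_wristband


@pytest.fixture(scope="session")
def quiet_params():
    """A subject with zero sensor noise (deterministic glucose dynamics)."""
    return SubjectParams("QUIET", glucose_noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 5 days with gaps applied, shared across tests."""
    return generate_cohort(3, 5, seed=42, wristband_excerpt_hours=0.25)


@pytest.fixture(scope="session")
def clean_wristband():
    """15 min of noise-free wristband waveforms with ground truth."""
    params = SubjectParams("WB", mean_ibi=0.85, ibi_sd=0.04, scr_rate=8.0, seed=5)
    return synthesize_wristband(params, 0.25)


@pytest.fixture
def flat_cgm():
    """A constant 120 mg/dL CGM day (no events)."""
    grid = regular_grid(pd.Timestamp("2024-03-01"), 288)
    return CgmSeries(grid, np.full(288, 120.0))


def make_cgm(values, start="2024-03-01"):
    values = np.asarray(values, float)
    return CgmSeries(regular_grid(pd.Timestamp(start), len(values)), values)


def make_events(rows):
    """rows: list of (iso_time, type, value, units)."""
    if not rows:
        return EventLog.empty()
    return EventLog(pd.DataFrame(
        [{"timestamp": pd.Timestamp(t), "type": k, "value": v, "units": u}
         for t, k, v, u in rows]))
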