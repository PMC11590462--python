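import numpy as np
import pandas as pd
import pytest

from movestrat.synthetic import SimConfig, simulate_ouf_track
from movestrat.track_io import Track


def make_track(times, lons, lats, bird_id="b1", **kwargs):
    fixes = pd.DataFrame(
        {"timestamp": pd.DatetimeIndex(times, tz="UTC"), "lon": lons, "lat": lats}
    )
    return Track(bird_id, fixes, **kwargs)


@pytest.fixture
def hourly_track():
    """24 hourly fixes moving due north ~1.08 km per step."""
    times = pd.date_range("2021-06-01", periods=24, freq="h", tz="UTC")
    lats = -30.0 + 0.00973 * np.arange(24)
    return make_track(times, np.full(24, 144.0), lats)


@pytest.fixture
def stationary_track():
    times = pd.date_range("2021-06-01", periods=40, freq="6h", tz="UTC")
    return make_track(times, np.full(40, 144.0), np.full(40, -30.0))


@pytest.fixture(scope="session")
def resident_month_track():
    """One 31-day exactly-simulated resident track (6-h fixes)."""
    return simulate_ouf_track(
        SimConfig(sigma2=100.0, tau_p=24.0, tau_v=1.0, fix_interval=6.0, duration=31.0, seed=7)
    )
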