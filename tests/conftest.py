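import numpy as np
import pandas as pd
import pytest

from kelpmhw.mhw import ClimatologyThreshold, DailySSTSeries, N_DOY


@pytest.fixture
def flat_climatology():
    """Flat seasonal mean 15 degC with a flat threshold at 16 degC."""
    return ClimatologyThreshold(
        clim_mean=np.full(N_DOY, 15.0),
        thresh90=np.full(N_DOY, 16.0),
        baseline=(1983, 2012),
    )


def make_series(sst_fn, start="1990-01-01", end="1991-12-31", cell_id="cell"):
    """Series from a function of day index."""
    dates = pd.date_range(start, end, freq="D")
    return DailySSTSeries(cell_id, dates, sst_fn(np.arange(len(dates))))


@pytest.fixture
def baseline_sinusoid_series():
    """30-year pure sinusoid covering the default 1983-2012 baseline."""
    dates = pd.date_range("1983-01-01", "2012-12-31", freq="D")
    t = np.arange(len(dates))
    sst = 15.0 + 4.0 * np.cos(2 * np.pi * (t - 200) / 365.25)
    return DailySSTSeries("sine", dates, sst)
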