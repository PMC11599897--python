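import numpy as np
import pytest

from paleocycles import CalibrationCurve, GridSeries, RadiocarbonDate
from paleocycles.growth import preprocess


@pytest.fixture
def identity_curve():
    return CalibrationCurve.identity(0.0, 20000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dates(ages, sd=30.0, site="s0", lon=10.0, lat=50.0):
    return [RadiocarbonDate(lab_id=f"L{i}", c14_age=float(a), c14_sd=sd,
                            lon=lon, lat=lat, site_id=site)
            for i, a in enumerate(ages)]


def noise_series(rng, n=120, step=100.0, t0=14900.0, preprocessed=True):
    g = GridSeries(t0, step, rng.standard_normal(n))
    return preprocess(g) if preprocessed else g


def sine_series(period, n=120, step=100.0, t0=14900.0, phase=0.0):
    t = t0 - step * np.arange(n)
    return GridSeries(t0, step, np.sin(2 * np.pi * t / period + phase))
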