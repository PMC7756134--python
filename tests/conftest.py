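import numpy as np
import pandas as pd
import pytest

from thickair import physiology, reconstruction, synthetic_data as sd


@pytest.fixture(scope="session")
def vo2_model():
    return physiology.calibrate_vo2_model()


@pytest.fixture(scope="session")
def climb_model(vo2_model):
    return physiology.calibrate_climb_model(vo2_model)


@pytest.fixture(scope="session")
def default_world():
    """Four years of hourly summit truth plus consistent level fields."""
    cfg = sd.SyntheticConfig(start="1995-01-01", end="1998-12-31T23:00", seed=42)
    series, truth = sd.generate_summit_series(cfg)
    fields = sd.generate_level_fields(series, config=cfg, truth=truth, n_lon=4)
    return cfg, series, truth, fields


@pytest.fixture(scope="session")
def event_world():
    """Ten winters with sharp, well-separated troughs for recovery tests."""
    cfg = sd.SyntheticConfig(
        start="1984-01-01", end="1993-12-31T23:00", seed=5,
        winter_sigma=0.4, summer_sigma=0.2, event_duration_days=2.0,
    )
    series, truth = sd.generate_summit_series(cfg)
    event_times = [pd.Timestamp(t) for t in truth.params["event_times"]]
    clim = reconstruction.doy_climatology(series)
    return cfg, series, event_times, clim


@pytest.fixture(scope="session")
def ensemble_world():
    cfg = sd.SyntheticConfig(seed=4)
    ensemble, global_t, truth = sd.generate_cmip_ensemble(cfg)
    return cfg, ensemble, global_t, truth
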