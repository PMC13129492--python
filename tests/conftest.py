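import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fedherd as fh

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def sensor_table(cattle_id="cow_000", start="2024-06-01T00:00:00",
                 interval_min=15, **columns) -> pd.DataFrame:
    """Build a minimal schema-conformant table from per-column lists."""
    n = len(next(iter(columns.values())))
    ts = pd.Timestamp(start) + pd.Timedelta(minutes=interval_min) * np.arange(n)
    base = {
        "timestamp": ts,
        "cattle_id": cattle_id,
        "heart_rate": 72.0,
        "body_temp": 38.5,
        "activity_level": 0.3,
        "ambient_temp": 20.0,
        "humidity": 60.0,
        "location_lat": 42.44,
        "location_long": -76.47,
        "is_stressed": np.nan,
    }
    df = pd.DataFrame(base | {}, index=range(n))
    for col, vals in columns.items():
        df[col] = vals
    return df


@pytest.fixture(scope="session")
def tiny_model_cfg() -> fh.ModelConfig:
    return fh.ModelConfig(
        n_features=8, window_len=8, cnn_channels=4, cnn_kernel=3,
        lstm_hidden=8, dense_hidden=8, seed=123,
    )


@pytest.fixture(scope="session")
def small_windows() -> fh.WindowedDataset:
    """A few hundred labelled windows from a small simulated herd."""
    cfg = fh.HerdSimConfig(n_animals=3, duration_hours=48, seed=5)
    table, _ = fh.simulate_herd(cfg)
    processed, _, _ = fh.preprocess_table(table)
    return fh.make_windows(processed, window_len=8, stride=2)
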