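"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from goosurv import pipeline, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-individual cohort with all four fates (deterministic)."""
    return synthetic.simulate_cohort(synthetic.ScenarioConfig(n_individuals=8, seed=11))


@pytest.fixture(scope="session")
def small_report(small_cohort):
    return pipeline.run_pipeline(pipeline.PipelineConfig(seed=11), cohort=small_cohort)


@pytest.fixture(scope="session")
def default_validation():
    """Full round trip on the default 40-individual scenario (the expensive one)."""
    return pipeline.simulate_and_validate(synthetic.ScenarioConfig())


def make_fixes(
    n_hours: int,
    start="2024-01-05T00:00:00Z",
    individual_id="X1",
    lon=116.2,
    lat=29.3,
    counts=50,
    device_temp=25.0,
    altitude=45.0,
    speed=1.0,
    accuracy="A",
    seed=0,
) -> pd.DataFrame:
    """Hand-built fix table with scalar or per-hour array fields."""
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start, periods=n_hours, freq="h", tz="UTC")

    def arr(v, dtype=float):
        a = np.asarray(v, dtype=dtype)
        return np.full(n_hours, a, dtype=dtype) if a.ndim == 0 else a

    return pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": ts,
            "longitude": arr(lon),
            "latitude": arr(lat),
            "speed": arr(speed),
            "heading": rng.uniform(0, 360, n_hours),
            "altitude": arr(altitude),
            "exercise_volume": arr(counts, dtype=np.int64),
            "device_temp": arr(device_temp),
            "voltage": 4.1,
            "accuracy": accuracy,
        }
    )


def make_weather(start="2023-12-20", days=400, temp=20.0) -> pd.DataFrame:
    dates = pd.date_range(start, periods=days, freq="D")
    t = np.full(days, float(temp))
    return pd.DataFrame(
        {
            "date": dates,
            "TEMP": t,
            "DEWP": t - 3.0,
            "SLP": 1018.0,
            "STP": 1013.0,
            "VISIB": 12.0,
            "WDSP": 3.5,
            "MXSPD": 6.0,
            "MAX": t + 4.0,
            "MIN": t - 4.0,
            "PRCP": 0.0,
        }
    )
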