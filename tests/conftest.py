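import numpy as np
import pandas as pd
import pytest

from smokepm import DomainConfig, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    """Reduced domain: quick to simulate, still exercises every stage."""
    return DomainConfig(
        nx=20,
        ny=20,
        n_hours=48,
        n_aqs=12,
        n_purpleair=60,
        n_pa_clusters=5,
        pa_collocated=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def pipeline(small_config):
    return run_pipeline(small_config)


def make_obs_frame(records):
    """Minimal ground-observation frame from (station, network, lon, lat,
    hour, pm25) tuples, with sensor covariates defaulted."""
    df = pd.DataFrame(
        records, columns=["station_id", "network", "lon", "lat", "hour", "pm25"]
    )
    df["temperature"] = 15.0
    df["relative_humidity"] = 50.0
    df["uptime"] = 10.0
    df["operating_time"] = 100.0
    df["cell_id"] = np.arange(len(df))
    return df
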