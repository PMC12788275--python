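import numpy as np
import pandas as pd
import pytest

from frailtylog.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_participants=8, seed=42, days=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def walking_log(speeds_or_n, dt: float = 1.0, t0: float = 0.0, activity: str = "WALKING"):
    """Straight synthetic log along a meridian with per-step speeds."""
    if np.isscalar(speeds_or_n):
        speeds = np.full(int(speeds_or_n), 1.2)
    else:
        speeds = np.asarray(speeds_or_n, dtype=float)
    n = len(speeds) + 1
    deg_per_m = 180.0 / (np.pi * 6_371_000.0)
    lat = 37.0 + np.concatenate([[0.0], np.cumsum(speeds * dt)]) * deg_per_m
    return pd.DataFrame(
        {
            "t": t0 + dt * np.arange(n),
            "lat": lat,
            "lon": np.full(n, 127.0),
            "activity": activity,
        }
    )
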