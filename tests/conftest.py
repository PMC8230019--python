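import datetime as dt

import numpy as np
import pandas as pd
import pytest

import olivephen as op


@pytest.fixture(scope="session")
def budbreak_flowering_model() -> op.DRModel:
    """Published linear calibration for budbreak (01) -> flowering (61)."""
    return op.bundled_calibration(1, 61)


def make_constant_weather(
    temp: float,
    site_id: str = "const",
    latitude: float = 40.0,
    start: dt.date = dt.date(1997, 1, 1),
    days: int = 500,
) -> op.DailyWeather:
    dates = pd.date_range(start, periods=days, freq="D")
    return op.DailyWeather(site_id, latitude, pd.Series(float(temp), index=dates))


@pytest.fixture
def constant_weather():
    return make_constant_weather


@pytest.fixture(scope="session")
def noisy_survey():
    """One synthetic survey at the study conditions (jitter 3.5 d, 20%
    missingness); shared across tests as it is deterministic for its seed."""
    observations, weather, truth = op.synthetic_survey(seed=42)
    return observations, weather, truth


@pytest.fixture(scope="session")
def noiseless_survey():
    """Synthetic survey with no survey jitter and complete event coverage."""
    observations, weather, truth = op.synthetic_survey(
        seed=7, sigma_obs=0.0, p_missing=0.0
    )
    return observations, weather, truth


def brute_force_phase_length(rates: np.ndarray) -> int | None:
    """Independent day-by-day scan: first n with sum of the first n daily
    rates >= 1, or None if the series is exhausted first."""
    total = 0.0
    for i, r in enumerate(rates):
        total += r
        if total >= 1.0:
            return i + 1
    return None
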