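import datetime as dt

import numpy as np
import pytest

from feverwatch.synthgen import DailyStream, ScenarioConfig


@pytest.fixture
def default_config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture
def quiet_config() -> ScenarioConfig:
    """No arrivals, no confounders: pure baseline + noise."""
    return ScenarioConfig(
        hourly_rate_profile=(0.0,) * 24,
        short_pass_rate=0.0,
        hot_object_rate=0.0,
    )


def make_stream(values, sample_rate=9.0, date=dt.date(2022, 4, 22)) -> DailyStream:
    """Short synthetic stream from explicit R1 values (R2 held at ambient)."""
    r1 = np.asarray(values, dtype=float)
    return DailyStream(
        date=date,
        sample_rate_hz=sample_rate,
        t_r1_max=r1,
        t_r2_mean=np.full_like(r1, 20.0),
    )


def random_walk_stream(rng, n_samples=540, sample_rate=9.0) -> DailyStream:
    """Random walk hovering around the 33 degC threshold; crosses it often."""
    steps = rng.normal(0.0, 0.6, size=n_samples)
    r1 = np.clip(33.0 + np.cumsum(steps), 26.0, 45.0)
    return make_stream(r1, sample_rate)
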