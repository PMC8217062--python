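import numpy as np
import pytest

from lithotherm import LaserSchedule, SystemConfig
from lithotherm.presets import set_a, set_b


@pytest.fixture
def set_a_cfg() -> SystemConfig:
    """Small-vessel preset: 5.89 mL, bath 37 degC, irrigation 23 degC, beta 1.15."""
    return set_a()


@pytest.fixture
def set_b_cfg() -> SystemConfig:
    """Kidney-scale preset: 38.3 mL, bath and irrigation 22 degC, beta 1.36."""
    return set_b()


@pytest.fixture
def burst_40w() -> LaserSchedule:
    """The standard acquisition burst: laser on at 20 s, off at 80 s, 40 W."""
    return LaserSchedule.single(20.0, 80.0, 40.0)


@pytest.fixture
def default_grid() -> np.ndarray:
    """Thermocouple-rate sampling of the standard 100 s protocol."""
    return np.arange(0.0, 100.0 + 1e-9, 0.1)


def random_config(rng: np.random.Generator) -> SystemConfig:
    """A physically plausible random vessel/irrigation configuration."""
    return SystemConfig.from_clinical(
        volume_ml=rng.uniform(2.0, 100.0),
        t0_c=rng.uniform(18.0, 40.0),
        beta_w_per_c=rng.uniform(0.2, 5.0),
        flow_ml_min=rng.uniform(0.0, 60.0),
        t_in_c=rng.uniform(15.0, 40.0),
    )


def random_schedule(rng: np.random.Generator, t_max: float = 200.0) -> LaserSchedule:
    """1-3 non-overlapping on-intervals with powers up to 60 W."""
    n = int(rng.integers(1, 4))
    span = t_max / (2.0 * n)
    cursor = 0.0
    intervals = []
    for _ in range(n):
        on = cursor + float(rng.uniform(0.5, span))
        off = on + float(rng.uniform(1.0, span))
        intervals.append((on, off, float(rng.uniform(5.0, 60.0))))
        cursor = off
    return LaserSchedule(intervals=tuple(intervals))
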