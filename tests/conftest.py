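import numpy as np
import pytest
from hypothesis import settings

from akialert.kdigo import Demographics, LabSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def demo_male_60() -> Demographics:
    return Demographics(age=60, sex="male")


@pytest.fixture
def flat_series():
    """Factory: flat creatinine series at a given level, 24 h apart."""

    def make(level: float = 0.8, n: int = 6, dt: float = 24.0) -> LabSeries:
        return LabSeries.from_arrays([i * dt for i in range(n)], [level] * n)

    return make


def random_series(rng: np.random.Generator, max_points: int = 12) -> LabSeries:
    """Random short series spanning up to ~10 days, SCr 0.4-3.5 mg/dL."""
    n = int(rng.integers(1, max_points + 1))
    times = np.sort(rng.uniform(0, 240, size=n))
    scrs = rng.uniform(0.4, 3.5, size=n)
    return LabSeries.from_arrays(times, scrs)
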