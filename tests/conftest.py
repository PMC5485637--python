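import numpy as np
import pytest

from peergaze.geometry import ScreenGeometry
from peergaze.preprocess import CleaningConfig
from peergaze.stream import GazeStream


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def cleaning() -> CleaningConfig:
    return CleaningConfig()


def make_stream(n: int = 300, rate_hz: float = 300.0,
                x: float = 960.0, y: float = 540.0,
                pupil: float = 4.0) -> GazeStream:
    """Constant stationary stream helper used across test modules."""
    t = np.arange(n) * 1000.0 / rate_hz
    ones = np.ones(n)
    return GazeStream(t, x * ones, y * ones, x * ones, y * ones,
                      pupil * ones, pupil * ones, np.ones(n, dtype=bool))


@pytest.fixture
def stationary_stream() -> GazeStream:
    return make_stream()
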