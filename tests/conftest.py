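import numpy as np
import pytest

from ergokit.core import ALL_MOTIONS, AngleSeries, JointMotion, RunConfig


def make_series(
    n: int = 10,
    sample_rate: float = 20.0,
    overrides: dict[JointMotion, float] | None = None,
    motions=ALL_MOTIONS,
) -> AngleSeries:
    """Constant-angle series, neutral except for the given overrides."""
    angles = {m: np.zeros(n) for m in motions}
    for motion, value in (overrides or {}).items():
        angles[motion] = np.full(n, float(value))
    return AngleSeries.from_columns(angles, sample_rate=sample_rate)


@pytest.fixture
def neutral_series() -> AngleSeries:
    return make_series(n=100)


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
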