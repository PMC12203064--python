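import numpy as np
import pytest

from commdyn.data_io import CommunityMatrix, EnvironmentSeries


@pytest.fixture
def small_cm():
    """A tiny two-station count table with irregular times."""
    counts = np.array(
        [
            [5, 0, 2, 7, 1, 0],
            [0, 3, 0, 1, 0, 4],
            [2, 2, 9, 0, 3, 3],
        ]
    )
    return CommunityMatrix(
        counts=counts,
        taxon_ids=["t1", "t2", "t3"],
        sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"],
        times=np.array([0.0, 31.0, 59.0, 0.0, 28.0, 63.0]),
        station=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
    )


@pytest.fixture
def irregular_times():
    """66 roughly monthly sampling days with +-7 day jitter."""
    rng = np.random.default_rng(42)
    return np.cumsum(np.r_[0.0, 28.0 + rng.integers(-7, 8, 65)]).astype(float)


@pytest.fixture
def seasonal_salinity(irregular_times):
    """Seasonal salinity series aligned to the irregular times."""
    rng = np.random.default_rng(7)
    doy = irregular_times % 365.25
    s = 26.0 + 5.0 * np.sin(2 * np.pi * doy / 365.25) + rng.standard_normal(len(doy))
    return np.clip(s, 0.0, None)


@pytest.fixture
def seasonal_env(irregular_times, seasonal_salinity):
    return EnvironmentSeries(
        sample_ids=[f"s{k:03d}" for k in range(len(irregular_times))],
        salinity=seasonal_salinity,
    )
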