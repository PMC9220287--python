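import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from betageo.data_model import OccurrenceMatrix, RegionTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_occ() -> OccurrenceMatrix:
    """5 species x 4 regions, mixed suborders, hand-checkable faunas."""
    inc = np.array([
        [1, 0, 1, 0],
        [1, 1, 1, 0],
        [1, 1, 0, 1],
        [0, 1, 1, 1],
        [0, 1, 0, 1],
    ])
    return OccurrenceMatrix(
        ["s1", "s2", "s3", "s4", "s5"],
        ["north", "mid", "south", "isle"],
        inc,
        ["Zygoptera", "Zygoptera", "Anisoptera", "Anisoptera", "Anisoptera"],
    )


@pytest.fixture
def small_regions() -> RegionTable:
    """4 regions strung north to south, one island."""
    return RegionTable(pd.DataFrame({
        "region_id": ["north", "mid", "south", "isle"],
        "name": ["north", "mid", "south", "isle"],
        "lat": [46.0, 43.0, 40.0, 38.0],
        "lon": [9.0, 11.0, 14.0, 13.0],
        "area": [15000.0, 12000.0, 18000.0, 25000.0],
        "pmean": [1050.0, 900.0, 700.0, 550.0],
        "tmean": [9.0, 12.0, 15.0, 18.0],
        "tmin": [1.0, 4.0, 7.0, 11.0],
        "tmax": [17.0, 20.0, 23.0, 25.0],
        "mainland": [True, True, True, False],
    }))


def random_distance_matrix(rng: np.random.Generator, labels):
    """Independent random symmetric zero-diagonal matrix (Mantel nulls)."""
    from betageo.data_model import DistanceMatrix

    n = len(labels)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(list(labels), v)
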