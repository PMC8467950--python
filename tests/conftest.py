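import numpy as np
import pytest

from guildflow import CountTable, SimConfig
from guildflow.core_io import SampleInfo


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        ["s1", "s2", "s3"],
        ["a", "b", "c", "d"],
        np.array([[5, 0, 3, 2], [1, 1, 1, 1], [0, 10, 0, 0]]),
    )


@pytest.fixture
def tiny_metadata() -> list[SampleInfo]:
    return [
        SampleInfo("s1", "m1", "control", 0, food=5.0, water=12.0, body_weight=30.0, glucose=200.0),
        SampleInfo("s2", "m2", "treated", 0, food=4.0, water=10.0, body_weight=28.0, glucose=180.0),
        SampleInfo("s3", "m1", "control", 14, food=5.5, water=13.0, body_weight=31.0, glucose=220.0),
    ]


@pytest.fixture
def small_sim_config() -> SimConfig:
    """Scaled-down study for fast unit tests."""
    return SimConfig(
        n_groups=3,
        mice_per_group=4,
        n_asvs=24,
        n_guilds=4,
        library_size_range=(1500, 2500),
        treatment_effects={(0, "GTE1", 14): 1.0, (0, "GTE1", 28): 1.5},
        gamma_glucose=(40.0, -40.0, 0.0, 0.0),
        gamma_weight=(2.0, 0.0, 3.0, 0.0),
        rng_seed=0,
    )


def random_distance_matrix(rng: np.random.Generator, n: int, low: float = 0.1, high: float = 2.0) -> np.ndarray:
    """Symmetric, zero-diagonal, non-negative random dissimilarities."""
    m = rng.uniform(low, high, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
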