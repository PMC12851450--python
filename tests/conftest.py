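import numpy as np
import pytest

from gliomalatt import anatomy


@pytest.fixture(scope="session")
def small_atlas():
    """24^3 full-grid brain with one slab tract and one straight vessel."""
    return anatomy.generate_synthetic_atlas(
        shape=(24, 24, 24),
        tract_specs=[{"kind": "slab", "axis": 2, "start": 16, "thickness": 3}],
        vessel_specs=[{"kind": "tube", "p0": (4, 4, 4), "p1": (20, 20, 4), "radius": 1.5}],
        seed=0,
        brain="full",
    )


@pytest.fixture(scope="session")
def open_atlas():
    """Large empty brain (no structures): unbiased dynamics, no boundary."""
    return anatomy.generate_synthetic_atlas(shape=(41, 41, 41), brain="full", seed=0)


@pytest.fixture(scope="session")
def bench_atlas():
    return anatomy.default_atlas((32, 32, 32), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
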