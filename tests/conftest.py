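import numpy as np
import pytest

from poissnap import CellGeometry, NondimParams


@pytest.fixture
def unit_geom() -> CellGeometry:
    """Unit domain with centered source (the standard inference benchmark)."""
    return CellGeometry(L=1.0, z=0.5)


@pytest.fixture
def bench_theta() -> NondimParams:
    """Benchmark rates used throughout the inference experiments."""
    return NondimParams(lam=500.0, mu=10.0)


@pytest.fixture
def traj_theta() -> NondimParams:
    """Rates of the trajectory-visualization setup (lam=10, mu=1.5)."""
    return NondimParams(lam=10.0, mu=1.5)


@pytest.fixture
def traj_geom() -> CellGeometry:
    return CellGeometry(L=3.0, z=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
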