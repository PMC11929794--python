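import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from insularity.geometry import Archipelago, IslandPolygon
from insularity.simulate import SimulationConfig, generate_bundle


def square(x0: float, y0: float, side: float) -> Polygon:
    return box(x0, y0, x0 + side, y0 + side)


@pytest.fixture
def toy_archipelago() -> Archipelago:
    """Five squares with known pairwise gaps; 'big' is the main island."""
    islands = [
        IslandPolygon("big", square(0, 0, 100)),
        IslandPolygon("a", square(150, 0, 10)),          # 50 m east of big
        IslandPolygon("b", square(0, 130, 20)),          # 30 m north of big
        IslandPolygon("c", square(300, 300, 5)),
        IslandPolygon("d", square(150, 20, 10), sampled=False),
    ]
    return Archipelago(islands, crs="toy-metric")


@pytest.fixture(scope="session")
def small_bundle():
    """One small but complete synthetic scene shared across tests."""
    cfg = SimulationConfig(
        seed=11, n_islands=10, n_unsampled=3,
        area_range=(2.5e3, 3e5), extent=5000, cell_size=10, min_gap=60,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_bundle(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
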