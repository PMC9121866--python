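import numpy as np
import pytest

from tigersim.agents import Params, Tiger
from tigersim.landscape import (CLASS_PRIMARY, CLASS_SECONDARY, PreyGrid,
                                RoadLayer)
from tigersim.territory import TerritoryMap


@pytest.fixture
def params():
    return Params()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_prey():
    """30x30 landscape with the Chitwan mean prey in every cell."""
    shape = (30, 30)
    return PreyGrid(production=np.full(shape, 3.78),
                    mask=np.ones(shape, dtype=bool))


@pytest.fixture
def no_roads():
    return RoadLayer(class_grid=np.zeros((30, 30), dtype=np.uint8))


def make_tmap(prey, roads=None):
    return TerritoryMap(prey.production, prey.mask, prey.cell_size,
                        road_class=None if roads is None else roads.class_grid)


def settled_female(tmap, fid=1, origin=(15, 15), age=60):
    f = Tiger(fid, "F", age, natal_center=origin)
    tmap.settle(fid, origin)
    f.territory_id = fid
    f.location = origin
    return f


@pytest.fixture
def road_cross():
    """30x30 road layer with a primary column and a secondary column."""
    grid = np.zeros((30, 30), dtype=np.uint8)
    grid[:, 5] = CLASS_PRIMARY
    grid[:, 20] = CLASS_SECONDARY
    return RoadLayer(class_grid=grid)
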