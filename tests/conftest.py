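import numpy as np
import pytest

from astroabm.kernel import InfluenceKernel
from astroabm.lattice import CellKind


@pytest.fixture(scope="session")
def kernel() -> InfluenceKernel:
    return InfluenceKernel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_grid(shape, tumors=(), anti=(), pro=(), neutral=()):
    """Small occupancy grid with agents at explicit sites."""
    occ = np.full(shape, CellKind.EMPTY, dtype=np.int8)
    for xy in tumors:
        occ[xy] = CellKind.TUMOR
    for xy in anti:
        occ[xy] = CellKind.ASTRO_ANTI
    for xy in pro:
        occ[xy] = CellKind.ASTRO_PRO
    for xy in neutral:
        occ[xy] = CellKind.NEUTRAL
    return occ
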