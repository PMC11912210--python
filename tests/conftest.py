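import numpy as np
import pytest
from hypothesis import settings

from ramaibi import AngleGrid, RamaDistribution

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_grid():
    return AngleGrid()


@pytest.fixture(scope="session")
def coarse_grid():
    """10-degree grid (1296 bins) for tests where resolution is irrelevant."""
    return AngleGrid(bin_width=10.0)


def random_distribution(grid: AngleGrid, rng: np.random.Generator) -> RamaDistribution:
    p = rng.random((grid.n_phi, grid.n_psi))
    return RamaDistribution(grid=grid, p=p / p.sum(), meta="histogram")
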