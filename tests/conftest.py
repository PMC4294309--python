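import numpy as np
import pytest

import paddygeo as pg


@pytest.fixture(scope="session")
def scenarios():
    """The packaged 27-scenario study table."""
    return pg.load_scenarios()


@pytest.fixture(scope="session")
def nh4_10_model():
    """Generating model of the control NH4-N dataset at sowing."""
    return pg.VariogramModel("spherical", 1.09, 14.20, 47.0)


@pytest.fixture(scope="session")
def nh4_10_field(nh4_10_model):
    """One seeded 93-point realization of the NH4-10 scenario."""
    cfg = pg.SimulationConfig(model=nh4_10_model, mean_level=20.07,
                              seed=2024, dataset_code="NH4-10")
    return pg.simulate_gaussian_field(cfg)


def random_scatter(seed, n, extent=100.0, low=1.0, high=30.0,
                   code="SCATTER"):
    """Irregular (non-lattice) positive-valued sample set for oracle tests."""
    rng = np.random.default_rng(seed)
    while True:
        xy = rng.uniform(0, extent, size=(n, 2)).round(3)
        if len({(a, b) for a, b in xy.tolist()}) == n:
            break
    values = rng.uniform(low, high, size=n)
    return pg.SampleSet(code, pg.Nutrient.NH4N, 0.0, 1,
                        xy[:, 0], xy[:, 1], values)


@pytest.fixture
def scatter_12():
    return random_scatter(7, 12)
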