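import numpy as np
import pytest

import ferticast as fc
from ferticast.config import MCMCConfig


@pytest.fixture(scope="session")
def small_panel():
    """3-region synthetic panel with fully observed transitions."""
    panel, truth = fc.generate_panel(fc.SyntheticSpec(n_regions=3, seed=11))
    return panel, truth


@pytest.fixture(scope="session")
def small_phases(small_panel):
    panel, _ = small_panel
    return {s.region_id: fc.assign_phases(s) for s in panel.series}


@pytest.fixture(scope="session")
def tiny_mcmc_config():
    return MCMCConfig(chains=2, iterations=400, burn_in=200, thin=2, seed=5)


@pytest.fixture(scope="session")
def small_sample(small_panel, small_phases, tiny_mcmc_config):
    panel, _ = small_panel
    return fc.run_mcmc(panel, small_phases, tiny_mcmc_config)


@pytest.fixture
def example_theta():
    return fc.DeclineParams(delta=(2.0, 1.0, 1.0, 2.0), d_max=1.0)


def make_series(values, start_year=1950, region_id="X"):
    values = np.asarray(values, dtype=float)
    grid = fc.PeriodGrid(start_year, len(values))
    return fc.TFRSeries(region_id, region_id, values, grid)
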