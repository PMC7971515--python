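import numpy as np
import pytest

import wormgnn as wg


@pytest.fixture(scope="session")
def small_population():
    """Four synthetic individuals, short recordings, default conditions."""
    cfg = wg.SyntheticPopulationConfig(n_individuals=4, n_timesteps=400)
    return wg.generate_population(cfg, master_seed=7)


@pytest.fixture(scope="session")
def labeled_traceset(small_population):
    return small_population[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
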