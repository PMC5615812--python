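import numpy as np
import pytest

from ersmix.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Raw-scale cohort: 400 subjects, 6 exposures in two blocks, sparse truth."""
    cfg = SimulationConfig(
        n=400,
        p=6,
        block_spec=[(3, 0.5), (3, 0.0)],
        beta_main={"metal_01": 0.3, "metal_05": -0.25},
        beta_inter={("metal_02", "metal_06"): 0.2},
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
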