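import numpy as np
import pytest

from canyonpool import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced two-slope cohort: 150 kb, one SFS-only sweep, defaults
    otherwise (9+9 lines, 40-haplotype pools, 73x depth)."""
    return SimulationConfig(
        genome_length=150_000,
        seed=5,
        sweep_intervals=[("2R", 40_001, 100_000, 0.3, "SFS")],
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
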