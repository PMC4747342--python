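import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fusionchip.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "default",
    settings(
        deadline=None,
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


SMALL_CFG = dict(
    chrom_lengths={"chr1": 700_000, "chr2": 500_000},
    n_genes=60,
    n_peaks=300,
    n_sets=80,
    set_size_range=(5, 15),
)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=7, **SMALL_CFG))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
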