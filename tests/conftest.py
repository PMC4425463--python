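import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from somamark import synthetic_data as sd

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_read_config():
    """Scaled-down read simulation: full mitochondrial genome, short
    nuclear proxy, typical study depth and copy number."""
    return sd.ReadSimConfig(nuclear_proxy_length=200_000,
                            mtdna_copies_per_cell=120.0,
                            nuclear_mean_depth=1.7, seed=11)


@pytest.fixture(scope="session")
def small_reads(small_read_config):
    return sd.simulate_reads(small_read_config)


@pytest.fixture(scope="session")
def state_dependent_cohort():
    config = sd.CohortConfig(
        n_samples=10_000,
        scenario=sd.CausalScenario.state_dependent(),
        telomere_scenario=sd.CausalScenario(
            sd.ScenarioKind.STATE_DEPENDENT, delta_md_marker=-0.163),
        seed=7)
    phenotypes, truth = sd.simulate_cohort(config)
    return phenotypes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
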