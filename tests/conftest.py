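import numpy as np
import pytest

from burdenqci import ScenarioConfig, generate_burden, generate_population


def flat_apc(value: float) -> dict[str, float]:
    return {m: value for m in ("incidence", "prevalence", "deaths", "dalys")}


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A quick noiseless scenario used by several modules."""
    return ScenarioConfig(years=(2000, 2015), noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config):
    pop = generate_population(small_config)
    burden = generate_burden(small_config, pop)
    return pop, burden


@pytest.fixture(scope="session")
def noisy_tables():
    cfg = ScenarioConfig(years=(2000, 2015), noise_cv=0.05, seed=3)
    pop = generate_population(cfg)
    return cfg, pop, generate_burden(cfg, pop)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
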