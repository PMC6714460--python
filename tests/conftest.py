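import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirhostnet import synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario() -> synthetic.SyntheticScenario:
    """A compact two-tissue scenario used across module tests."""
    return synthetic.SyntheticScenario(
        n_genes=300,
        n_targets_per_predictor=40,
        tissues=("cardiac_muscle", "skin"),
        n_gene_sets=30,
        gene_set_size_range=(5, 15),
        planted_set_overlap=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario) -> synthetic.ScenarioBundle:
    return synthetic.generate_scenario(small_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
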