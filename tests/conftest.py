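import numpy as np
import pytest

from admincost import estimators, simulation
from admincost.synthetic_data import GeneratorConfig, generate_product_sample, reference_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Printed study constants (product roster, coefficient tables, smearing)."""
    return reference_fixtures()


@pytest.fixture(scope="session")
def sample18():
    """Default 18-product synthetic sample (8 IV, 8 SC, 2 IM)."""
    return generate_product_sample(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def simulated18(sample18):
    """Per-product simulation table for the default sample."""
    products = [p for p, _ in sample18]
    breakdowns = [b for _, b in sample18]
    return simulation.simulate_products(
        products, breakdowns, simulation.SimulationConfig(n_draws=1000, seed=7)
    )


@pytest.fixture(scope="session")
def fit18(sample18, simulated18):
    """Full-model log-OLS fit to the simulated mean costs."""
    products = [p for p, _ in sample18]
    X = estimators.build_design(products, "C")
    y = np.log(simulated18["mean_sim_cost"].to_numpy())
    return estimators.fit_log_ols(X, y)
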