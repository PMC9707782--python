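import numpy as np
import pandas as pd
import pytest

from beartrack.simulate import TruthConfig, generate_study


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration synthetic study, shared across tests."""
    return generate_study(seed=7)


@pytest.fixture(scope="session")
def small_zinb_dataset():
    """A 20-site simulated count dataset with known truth parameters."""
    rng = np.random.default_rng(42)
    n_sites, n_months = 20, 13
    data = pd.DataFrame({
        "site_id": np.repeat([f"S{i:02d}" for i in range(n_sites)], n_months),
        "effort": rng.integers(15, 31, n_sites * n_months),
        "x1": rng.standard_normal(n_sites * n_months),
    })
    u = 0.7 * rng.standard_normal(n_sites)
    mu = np.exp(-1.0 + 0.5 * data["x1"] + np.repeat(u, n_months)) * data["effort"]
    theta = 0.8
    y = rng.negative_binomial(theta, theta / (theta + mu))
    y = np.where(rng.uniform(size=len(mu)) < 0.3, 0, y)
    data["count"] = y
    truth = {"beta": [-1.0, 0.5], "theta": theta, "pi": 0.3, "sigma": 0.7}
    return data, truth
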