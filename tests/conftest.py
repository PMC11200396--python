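import numpy as np
import pandas as pd
import pytest

from isobolo.simulate import SimulationConfig, simulate_ogdr_experiment


@pytest.fixture(scope="session")
def additive_experiment():
    """One noisy simulated experiment with an additive (psi = 1) mixture."""
    return simulate_ogdr_experiment(SimulationConfig(psi=1.0, seed=42))


@pytest.fixture(scope="session")
def synergy_experiment():
    """One noisy simulated experiment with strong synergy (psi = 0.1)."""
    return simulate_ogdr_experiment(SimulationConfig(psi=0.1, seed=42))


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Noise-free additive experiment: every derived value is exact."""
    return simulate_ogdr_experiment(SimulationConfig(psi=1.0, noise_sd=0.0, seed=0))


@pytest.fixture()
def small_ldh_plate():
    """Minimal LDH plate: blank 0.1, maximum 1.1, one treated group at 0.6."""
    rows = []
    for rep in (1, 2, 3):
        rows.append(("blank", "none", 0.0, rep, "ldh", 0.1))
        rows.append(("maximum_release", "none", 0.0, rep, "ldh", 1.1))
        rows.append(("ogdr_treated", "DDS", 7.55, rep, "ldh", 0.6))
    return pd.DataFrame(
        rows, columns=["group", "drug_id", "concentration_uM", "replicate", "assay", "signal"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
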