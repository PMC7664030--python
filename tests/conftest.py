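import numpy as np
import pandas as pd
import pytest

from qsmart import SimulationSpec, simulate_bundle
from qsmart.io import FeatureMatrix


@pytest.fixture(scope="session")
def default_bundle():
    """One default-conditions synthetic bundle shared across tests."""
    return simulate_bundle(SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for fast end-to-end checks."""
    spec = SimulationSpec(seed=11, n_drugs=35, n_cell_lines=30)
    return simulate_bundle(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_matrix():
    """Minimal feature matrix: two drug bits, one residue, one expression."""
    rng = np.random.default_rng(3)
    n = 60
    values = pd.DataFrame({
        "Fingerprint_10": rng.binomial(1, 0.5, n).astype(float),
        "Fingerprint_800": rng.binomial(1, 0.5, n).astype(float),
        "PKA_187_CHA": rng.choice([0.0, 1.0, 2.0], n),
        "EXP_AAA": np.exp(rng.normal(0, 0.5, n)),
        "EXP_BBB": np.exp(rng.normal(0, 0.5, n)),
    })
    levels = {"Fingerprint_10": "drug", "Fingerprint_800": "drug",
              "PKA_187_CHA": "residue", "EXP_AAA": "gene",
              "EXP_BBB": "gene"}
    return FeatureMatrix(values, levels)
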