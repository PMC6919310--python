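import numpy as np
import pandas as pd
import pytest

from visitjm import PanelDataset, ScenarioConfig, simulate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def joint_data():
    """One moderately informative joint-model dataset, n = 200."""
    cfg = ScenarioConfig(dgm_kind="joint", lam=0.30, gamma_assoc=1.5, seed=314)
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def null_data():
    """Joint-model dataset with gamma = 0 (non-informative visiting)."""
    cfg = ScenarioConfig(dgm_kind="joint", lam=0.30, gamma_assoc=0.0, seed=2718)
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def small_data():
    """Small dataset for fast estimator plumbing tests."""
    cfg = ScenarioConfig(dgm_kind="joint", lam=0.30, gamma_assoc=1.0,
                         n_individuals=40, seed=99)
    return simulate_scenario(cfg)


def make_panel(rows):
    """Build a PanelDataset from (id, j, t, gap, d, y, Z, C) tuples."""
    df = pd.DataFrame(rows, columns=["id", "j", "t", "gap", "d", "y", "Z", "C"])
    return PanelDataset(data=df)
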