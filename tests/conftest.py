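import numpy as np
import pandas as pd
import pytest

from tmesf.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (8 samples x 150 cells, 300 genes)."""
    cfg = SimulationConfig(seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for structural tests."""
    cfg = SimulationConfig(seed=3, n_samples=6, cells_per_sample=60, n_genes=60,
                           n_state_genes=12)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_proportions():
    """Hand-built samples x subtypes proportion table with a missing parent."""
    from tmesf.proportions import ProportionTable

    table = pd.DataFrame(
        {
            "mregDC": [0.25, 0.4, np.nan, 0.1, 0.3],
            "cDC1": [0.5, 0.3, np.nan, 0.6, 0.4],
            "cDC2": [0.25, 0.3, np.nan, 0.3, 0.3],
        },
        index=pd.Index([f"S{i}" for i in range(5)], name="sample_id"),
    )
    return ProportionTable(table=table, parent_map={"mregDC": "cDC", "cDC1": "cDC", "cDC2": "cDC"})


def balanced_accuracy(z_hat: np.ndarray, z_true: np.ndarray) -> float:
    se = (z_hat[z_true == 1] == 1).mean() if (z_true == 1).any() else np.nan
    sp = (z_hat[z_true == 0] == 0).mean() if (z_true == 0).any() else np.nan
    return 0.5 * (se + sp)


def aligned_balanced_accuracy(z_hat: np.ndarray, z_true: np.ndarray) -> tuple[float, int]:
    """Balanced accuracy after polarity alignment; returns (accuracy, sign)."""
    a = balanced_accuracy(z_hat, z_true)
    b = balanced_accuracy(1 - z_hat, z_true)
    return (a, 1) if a >= b else (b, -1)
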