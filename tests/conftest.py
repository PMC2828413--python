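import numpy as np
import pandas as pd
import pytest

from anchorsig.io import ClinicalTable, ExpressionMatrix
from anchorsig.simulate import SimulationConfig, simulate_cohort


def make_matrix(values, feature_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(nf)]
    sample_ids = sample_ids or [f"s{j}" for j in range(ns)]
    return ExpressionMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))


def random_matrix(rng, n_features, n_samples) -> ExpressionMatrix:
    return make_matrix(rng.normal(size=(n_features, n_samples)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with a clear two-cluster structure (fast LOOCV)."""
    cfg = SimulationConfig(n_samples=40, n_features=300, n_module_features=60, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default study conditions (n=103, 5000 features)."""
    return simulate_cohort(SimulationConfig(seed=11))


def make_clinical(rng, sample_ids) -> ClinicalTable:
    n = len(sample_ids)
    return ClinicalTable(
        pd.DataFrame(
            {
                "time_months": rng.exponential(40.0, n) + 0.1,
                "event": rng.integers(0, 2, n),
                "stage": rng.choice(["Ta", "T1"], n),
                "grade": rng.choice(["low", "high"], n),
                "n_tumors": rng.choice(["single", "2to7", "ge8"], n),
                "size_gt3cm": rng.integers(0, 2, n),
                "intravesical_therapy": rng.integers(0, 2, n),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
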