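import numpy as np
import pytest

from neuroar.cohort import (CohortConfig, ParcelTimeSeries, generate_cohort,
                            make_coupling, simulate_run)
from neuroar.graphs import Connectome, random_connectome, scaled_laplacian
from neuroar.preprocess import zscore_per_run


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 12 parcels, 6 movie + 2 rest runs of 240 points."""
    cfg = CohortConfig(n_subjects=3, n_parcels=12,
                       n_runs_per_condition={"movie": 6, "rest": 2},
                       run_length=240, subject_divergence=0.5, seed=11)
    runs, truth = generate_cohort(cfg)
    return cfg, runs, truth


@pytest.fixture(scope="session")
def var1_system():
    """A stable VAR(1) generator with its support graph."""
    couplings, support = make_coupling(10, 0.3, 1, 0.8, seed=21)
    return couplings, support


@pytest.fixture(scope="session")
def var1_runs(var1_system):
    couplings, _ = var1_system
    train = [zscore_per_run(simulate_run(couplings, None, 1.0, 400, seed=100 + r,
                                         run=f"run-{r:02d}"))
             for r in range(3)]
    test = [zscore_per_run(simulate_run(couplings, None, 1.0, 400, seed=200 + r,
                                        run=f"run-{r:02d}"))
            for r in range(2)]
    return train, test


@pytest.fixture(scope="session")
def small_spectral_op():
    return scaled_laplacian(random_connectome(6, 0.4, seed=2))


def support_connectome(support: np.ndarray) -> Connectome:
    P = support.shape[0]
    return Connectome(adjacency=support.astype(np.uint8),
                      density=float(support.sum() / (P * (P - 1))),
                      kind="functional")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_series(data, tr=1.49, subject="sub-01", run="run-00", condition="movie"):
    return ParcelTimeSeries(subject=subject, run=run, condition=condition,
                            data=np.asarray(data, dtype=float), tr=tr)
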