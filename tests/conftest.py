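import numpy as np
import pandas as pd
import pytest

from slcm import QuadSpec, SimDesign, default_truth, fit_slcm, simulate_dataset


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240918)


@pytest.fixture(scope="session")
def dataset300():
    """One N=300 dataset from the stated testing truth."""
    return simulate_dataset(SimDesign(N=300), seed=7)


@pytest.fixture(scope="session")
def fit300(dataset300):
    """A converged reference fit (5 nodes/dim, with model-based + robust SEs).

    Shared across model tests to keep the suite inside its time budget.
    """
    fit = fit_slcm(dataset300, quad=QuadSpec(nodes_per_dim=5))
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def small_fit():
    """A quick low-resolution fit for structural (non-numeric) checks."""
    data = simulate_dataset(SimDesign(N=120), seed=3)
    fit = fit_slcm(data, quad=QuadSpec(nodes_per_dim=3), compute_se=False)
    return data, fit


@pytest.fixture()
def toy_bin():
    """A 10-record single-bin table with known totals."""
    return pd.DataFrame({
        "id": range(10),
        "bin_t": 0.0,
        "count": [0, 1, 0, 2, 1, 3, 0, 1, 2, 0],
        "exposure": [50, 80, 60, 120, 90, 150, 40, 70, 110, 55],
    })
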