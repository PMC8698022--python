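import numpy as np
import pytest

from scsol.datasets import SolubilityDataset
from scsol.eos import co2_density
from scsol.synthetic import PENG_OUTLIERS, generate, penicillin_fixture


@pytest.fixture(scope="session")
def peng_noiseless():
    """Noiseless penicillin-G-shaped dataset plus its generating truth."""
    ds, truth = generate(penicillin_fixture("penG", noise_cv=0.0))
    return ds, truth


@pytest.fixture(scope="session")
def peng_with_outliers():
    """Noiseless penG dataset with the standard two-point perturbation."""
    ds, truth = generate(penicillin_fixture("penG", noise_cv=0.0,
                                            outliers=PENG_OUTLIERS))
    return ds, truth


@pytest.fixture(scope="session")
def mst_consistent_dataset():
    """Dataset generated exactly from an MST single-line collapse.

    T ln(y2 P) = A + B rho + C T with densities from the PR EoS, so the
    MST fit must recover (A, B, C) exactly and the consistency check must
    see a perfect line.
    """
    A, B, C = -11_000.0, 3.0, 26.0
    T = np.repeat([313.15, 323.15, 333.15], 6)
    P = np.tile([100.0, 150.0, 200.0, 250.0, 300.0, 350.0], 3) * 1e5
    rho = np.array([co2_density(t, p) for t, p in zip(T, P)])
    y2 = np.exp((A + B * rho + C * T) / T) / P
    ds = SolubilityDataset.from_arrays(T, P, y2, rho)
    return ds, (A, B, C)
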