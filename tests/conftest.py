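"""Shared fixtures: the default synthetic study and one test-scale fit."""

import numpy as np
import pytest

import habitatipm as hp
from habitatipm.fit import fit_ipm


@pytest.fixture(scope="session")
def default_dataset() -> hp.SimulatedDataset:
    """The default 24-year study fixture (study-like rates and effort)."""
    return hp.simulate_dataset(hp.SimulationConfig())


@pytest.fixture(scope="session")
def fixture_fit(default_dataset):
    """One test-scale posterior fit on the default fixture, shared by the
    LTRE / elasticity / diagnostic tests."""
    return fit_ipm(default_dataset.observed, chains=2, iterations=1200,
                   burnin=600, seed=11)


def random_annual_params(rng: np.random.Generator,
                         with_omega: bool = False) -> hp.AnnualParams:
    """A random valid parameter set for property tests."""
    def psi():
        s = rng.uniform(0.05, 0.95, size=2)
        return np.column_stack([s, 1 - s])

    return hp.AnnualParams(
        b=rng.uniform(0.05, 0.95, (2, 2)),
        fled=rng.uniform(0.6, 2.5, (2, 2)),
        phi_fl=rng.uniform(0.01, 0.4, 2),
        phi_succ=rng.uniform(0.1, 0.9, (2, 2)),
        phi_fail=rng.uniform(0.1, 0.9, (2, 2)),
        psi_fl=psi(), psi_succ=psi(), psi_fail=psi(),
        omega=rng.uniform(0, 0.3, (2, 2)) if with_omega else np.zeros((2, 2)),
        p=rng.uniform(0.3, 1.0), c=rng.uniform(0.3, 1.0))
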