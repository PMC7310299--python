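import numpy as np
import pytest

from connmix import (
    ConnectivityDataset,
    CovariateTable,
    MixtureParameters,
    PriorSpec,
    simulate_dataset,
)
from connmix.gibbs import MCMCConfig, run_chain


def make_covariates(n: int, seed: int = 0) -> CovariateTable:
    """Intercept + standardized continuous covariate + binary covariate."""
    rng = np.random.default_rng(seed)
    age = rng.normal(size=n)
    age = (age - age.mean()) / age.std(ddof=1)
    sex = rng.integers(0, 2, n).astype(float)
    x = np.column_stack([np.ones(n), age, sex])
    return CovariateTable(x, ["intercept", "age", "sex"])


def make_true_params(n: int) -> MixtureParameters:
    """Population values used across simulation-based tests: moderate
    connectivity (~8-12% connected), tight non-connected component."""
    return MixtureParameters(
        alpha=[-0.7, 0.1, 0.2],
        delta=[-1.4, 0.3, 0.2],
        a=np.zeros(n),
        d=np.zeros(n),
        mu0=np.zeros(n),
        sigma0_sq=np.full(n, 0.01),
        sigma1_sq=np.full(n, 0.25),
        gamma_a_sq=0.04,
        gamma_d_sq=0.04,
    )


@pytest.fixture(scope="session")
def covariates10():
    return make_covariates(10, seed=0)


@pytest.fixture(scope="session")
def true_params10():
    return make_true_params(10)


@pytest.fixture(scope="session")
def simulated10(covariates10, true_params10):
    """(dataset, latent) at n=10 subjects, m=400 pairs."""
    return simulate_dataset(
        true_params10, covariates10, 400, seed=42, draw_random_effects=True
    )


@pytest.fixture(scope="session")
def fitted10(simulated10, covariates10):
    """A short but converged-enough posterior fit shared across tests."""
    data, _ = simulated10
    config = MCMCConfig(
        n_iterations=600, burn_in=300, thinning=2, n_chains=2, seed=7
    )
    return run_chain(data, covariates10, PriorSpec(), config)
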