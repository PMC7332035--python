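import numpy as np
import pandas as pd
import pytest

from pondstress.simulate import pond_survey_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """The 21-pond x 48-variable survey-like dataset (default seed)."""
    return pond_survey_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_poisson_instance(rng, n_ponds=30, n_vars=5, betas=None,
                            intercept=2.0, sigma=0.0):
    """Small dataset: uniform [0,1] covariates and Poisson counts."""
    X = pd.DataFrame(
        rng.uniform(0.0, 1.0, (n_ponds, n_vars)),
        columns=[f"v{i}" for i in range(n_vars)],
    )
    eta = np.full(n_ponds, float(intercept))
    if betas:
        for name, b in betas.items():
            eta += b * X[name].to_numpy()
    if sigma > 0:
        eta = eta + rng.normal(0.0, sigma, n_ponds)
    y = rng.poisson(np.exp(eta))
    return X, y
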