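import numpy as np
import pytest

from nbgmifs import CountGMIFS, nb_sample


@pytest.fixture(scope="session")
def small_nb_problem():
    """A small over-dispersed dataset with known truth (N=40, K=20)."""
    rng = np.random.default_rng(2024)
    n, k = 40, 20
    X = rng.standard_normal((n, k))
    beta = np.zeros(k)
    beta[[0, 3, 7]] = [0.6, -0.6, 0.5]
    mu = np.exp(0.4 + X @ beta)
    y = nb_sample(mu, 0.4, rng)
    return {"X": X, "y": y, "beta": beta, "alpha": 0.4, "gamma0": 0.4}


@pytest.fixture(scope="session")
def small_nb_path(small_nb_problem):
    """Fitted GMIFS path on the small problem (shared; ~2 s)."""
    model = CountGMIFS(
        small_nb_problem["y"], X_penalized=small_nb_problem["X"], family="negbin"
    )
    return model.fit()
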