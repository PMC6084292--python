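import numpy as np
import pytest

from cohosem import McmcConfig, fit, make_fixture
from cohosem.synthetic_data import FULL_STRUCTURE


@pytest.fixture(scope="session")
def tiny_ds():
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_post(tiny_ds):
    """A reasonably well-mixed fit of the tiny fixture, shared across tests."""
    return fit(
        tiny_ds,
        FULL_STRUCTURE,
        mcmc=McmcConfig(chains=2, warmup=700, draws=1500, seed=11),
    )


def make_constant_post(
    n_subbasins=4,
    n_monitored=2,
    n_samples=50,
    gamma0=(0.0, 0.0, 0.0),
    gamma_z=(0.0, 0.0, 0.0),
    sigma_beta=(0.0, 0.0, 0.0),
    sigma_delta=0.0,
    z=None,
):
    """A degenerate PosteriorDraws whose draws are all identical.

    Useful for exercising prediction/selection code paths against exact
    hand-computable answers.
    """
    from cohosem.inference import PosteriorDraws
    from cohosem.sem_core import ModelStructure, Priors, VariableSpec

    cd = (1, n_samples)
    S = n_subbasins
    if z is None:
        z = np.zeros(S)
    z = np.asarray(z, float)
    post = {
        "a0": np.zeros((*cd, 3)),
        "loadings": np.ones((*cd, 3, 1)),
        "sigma": np.ones((*cd, 1)),
        "shape": np.ones((*cd, 2)),
        "z": np.broadcast_to(z[None, None, :, None], (*cd, S, 1)).copy(),
        "gamma0": np.broadcast_to(np.asarray(gamma0, float), (*cd, 3)).copy(),
        "gamma_z": np.broadcast_to(
            np.asarray(gamma_z, float)[:, None], (*cd, 3, 1)
        ).copy(),
        "sigma_beta": np.broadcast_to(np.asarray(sigma_beta, float), (*cd, 3)).copy(),
        "v": np.zeros((*cd, 3, n_monitored)),
        "sigma_delta": np.full(cd, float(sigma_delta)),
        "delta": np.zeros((*cd, 0)),
    }
    ids = np.array([f"sb{i:04d}" for i in range(S)])
    return PosteriorDraws(
        posterior=post,
        structure=ModelStructure("z", "z", "z"),
        specs=[
            VariableSpec("g1", "gamma"), VariableSpec("g2", "gamma"),
            VariableSpec("p1", "proportion"),
        ],
        landscape_ids=ids,
        survey_subbasins=ids[:n_monitored],
        sample_stats={},
        seed=0,
        priors=Priors(),
    )
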