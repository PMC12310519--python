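import numpy as np
import pytest

from sgmkit.forward import FrequencyGrid, SGMParameters
from sgmkit.inference import PriorBox
from sgmkit.synthetic import make_connectome


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def conn16():
    return make_connectome(16, seed=3)


@pytest.fixture(scope="session")
def conn12():
    return make_connectome(12, seed=1)


@pytest.fixture(scope="session")
def prior() -> PriorBox:
    return PriorBox.default()


@pytest.fixture(scope="session")
def midpoint() -> SGMParameters:
    return SGMParameters.midpoint()


@pytest.fixture(scope="session")
def trained_npe(conn16, grid, prior):
    """Amortized posterior shared across inference/diagnostics tests.

    Trained once per session on 2000 noisy simulations of the 16-region
    synthetic connectome.
    """
    from sgmkit.inference import sample_prior, simulate_batch, train_npe

    thetas = sample_prior(prior, 2000, seed=21)
    batch = simulate_batch(thetas, conn16, grid, noise_sigma=0.1, seed=22)
    return train_npe(prior, batch.thetas, batch.summaries, seed=23)


def replace_param(params: SGMParameters, **kwargs) -> SGMParameters:
    vals = {name: getattr(params, name) for name in
            ("tau_e", "tau_i", "alpha", "speed", "g_ei", "g_ii", "tau_g")}
    vals.update(kwargs)
    return SGMParameters(**vals)
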