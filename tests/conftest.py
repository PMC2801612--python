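import numpy as np
import pytest

from pxkinetics import FitConfig, ModelParameters


@pytest.fixture
def params():
    """A generic mid-range parameter set."""
    return ModelParameters(
        f=10.0, r0=0.2, t_rise=1.5, t_fall=3.0, tau_rise=0.5, tau_fall=2.0, eta=3.0
    )


def constant_rate_params(r0: float, f: float = 0.0) -> ModelParameters:
    """Parameters whose rate is constant r0 for all finite times.

    Pushing the logistic midpoints far out flattens both sigmoids to 1
    over any window of interest.
    """
    return ModelParameters(
        f=f, r0=r0, t_rise=-1e6, t_fall=1e6, tau_rise=1.0, tau_fall=1.0, eta=3.0
    )


@pytest.fixture
def small_config():
    """A short but functional sampler configuration for fast tests."""
    return FitConfig(n_equilibration=4000, n_production=2000, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
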