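import pytest
from hypothesis import settings, HealthCheck

from fpreduce import NeuronParams
from fpreduce.tables import GridSpec, precompute_quantities

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def neuron():
    """Cortical-pyramidal aEIF parameter set used throughout."""
    return NeuronParams()


@pytest.fixture(scope="session")
def eif():
    """Detached EIF membrane: adaptation disabled."""
    return NeuronParams(a=0.0, b=0.0)


@pytest.fixture(scope="session")
def suite_table(eif):
    """Shared quantity table for model and benchmark tests.

    Moderate resolutions keep the whole-suite runtime reasonable while
    staying quantitatively close to the production settings (the tabulated
    eigenvalues are converged to ~6 digits already at this voltage
    spacing).
    """
    gs = GridSpec(mu_min=-2.0, mu_max=4.5, d_mu=0.25,
                  sigma_min=1.0, sigma_max=2.5, d_sigma=0.25)
    return precompute_quantities(eif, gs, dV_stationary=0.02,
                                 dV_spectral=0.02, dV_cascade=0.1,
                                 n_freq=32)
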