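import numpy as np
import pytest

from pfcwm import NetworkSpec, build_layout, sample_connectivity


@pytest.fixture(scope="session")
def tiny_spec():
    """A small but structurally complete network (fast to build and run)."""
    return NetworkSpec(N_E=400, N_I=100, p=5, f=0.1, c=0.3)


@pytest.fixture(scope="session")
def tiny_layout(tiny_spec):
    return build_layout(tiny_spec)


@pytest.fixture(scope="session")
def tiny_table(tiny_spec, tiny_layout):
    return sample_connectivity(tiny_spec, tiny_layout, seed=123)


@pytest.fixture(scope="session")
def single_neuron_factory():
    """Isolated single-neuron 'networks' (one E, one I, no synapses)."""

    def make(mu_E=0.0, sigma_E=0.0):
        return NetworkSpec(
            N_E=1, N_I=1, p=1, f=1.0, c=0.0,
            mu_ext=(mu_E, 0.0), sigma_ext=(sigma_E, 0.0),
        )

    return make
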