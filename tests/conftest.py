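import numpy as np
import pytest
from hypothesis import settings

from dichropam import PhantomSpec, make_stack

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def uniform_spec():
    """8x8 phantom: a=1, b=1, phi=30 deg, no noise, no drift."""
    shape = (8, 8)
    return PhantomSpec(
        orientation_field=np.full(shape, 30.0),
        iso_map=np.ones(shape),
        dichroic_map=np.ones(shape),
        seed=1,
    )


@pytest.fixture
def uniform_stack(uniform_spec):
    stack, truth = make_stack(uniform_spec)
    return stack, truth


def grid_spec(seed=0, noise_sigma=0.0):
    """Every pixel a distinct (a, b, phi) combination over a dense grid."""
    a_vals = np.array([0.5, 1.0, 2.0, 5.0])
    b_vals = np.arange(0.0, 2.01, 0.25)
    phi_vals = np.arange(-90.0, 90.0, 5.0)
    aa, bb, pp = np.meshgrid(a_vals, b_vals, phi_vals, indexing="ij")
    shape = aa.shape[0] * aa.shape[1], aa.shape[2]
    return PhantomSpec(
        orientation_field=pp.reshape(shape),
        iso_map=aa.reshape(shape),
        dichroic_map=bb.reshape(shape),
        noise_sigma=noise_sigma,
        seed=seed,
    )
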