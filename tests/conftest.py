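"""Shared fixtures: point groups, phantoms and small simulated stacks.

Everything is generated programmatically at run time from explicit seeds; no
binary fixtures are stored.  Session scope keeps the expensive objects (the
icosahedral group, the 96-box phantom) built once.
"""

import numpy as np
import pytest

from vertexrec.phantom import PhantomSpec, build_phantom
from vertexrec.simulate import simulate_particles
from vertexrec.symmetry import build_point_group, vertex_axes


@pytest.fixture(scope="session")
def icos_group():
    return build_point_group("I")


@pytest.fixture(scope="session")
def vertices(icos_group):
    return vertex_axes(icos_group)


@pytest.fixture(scope="session")
def phantom():
    """Default-geometry phantom with seeded random vertex azimuths."""
    rng = np.random.default_rng(42)
    return build_phantom(PhantomSpec().random_azimuths(rng))


@pytest.fixture(scope="session")
def clean_stack(phantom):
    """Small noise-free, CTF-free stack for exactness tests."""
    return simulate_particles(phantom, 6, seed=101, noise_sigma=0.0,
                              with_ctf=False)


@pytest.fixture(scope="session")
def ctf_stack(phantom):
    """Small noise-free stack with CTF for modulation-aware tests."""
    return simulate_particles(phantom, 6, seed=202, noise_sigma=0.0,
                              with_ctf=True)
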