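"""Shared fixtures: phantoms are generated once per session."""

import numpy as np
import pytest

from ebusreg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The default straight-tube phantom (160x160x200 @ 0.7 mm)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced phantom for cheap unit tests."""
    spec = PhantomSpec(shape=(80, 80, 100), inner_radius=6.0,
                       node_semi_axes=(5.0, 6.0, 5.5), seed=3)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
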