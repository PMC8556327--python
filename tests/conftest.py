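"""Shared fixtures: synthetic ring assemblies with known ground truth."""

import numpy as np
import pytest

from phycoring.synthetic import (HEXAMER_LIKE, OCTAMER_LIKE, RingSpec,
                                 build_ring)


@pytest.fixture(scope="session")
def hexamer_ring():
    """Jitter-free D3 double ring with the hexamer-like construction angles."""
    return build_ring(HEXAMER_LIKE)


@pytest.fixture(scope="session")
def octamer_ring():
    """Jitter-free D4 double ring with the octamer-like construction angles."""
    return build_ring(OCTAMER_LIKE)


@pytest.fixture(scope="session")
def c4_ring():
    """Jitter-free single-layer C4 ring."""
    return build_ring(RingSpec(n=4, layers=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
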