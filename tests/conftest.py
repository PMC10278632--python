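"""Shared fixtures: expensive seeded Monte-Carlo artefacts built once."""

import numpy as np
import pytest

from sfdi_forge.dis import get_slab_forward_model
from sfdi_forge.optics import OpticalProperties
from sfdi_forge.phantoms import TISSUES
from sfdi_forge.sfdi import build_model_lut


@pytest.fixture(scope="session")
def slab_forward():
    """Monte-Carlo slab forward model (1 mm, g=0.8, n=1.4), session-cached."""
    return get_slab_forward_model()


@pytest.fixture(scope="session")
def model_lut():
    """Diffusion-forward model LUT at fx=0.2 over the standard ranges."""
    return build_model_lut(0.2)


@pytest.fixture(scope="session")
def healthy():
    return TISSUES["healthy"]


@pytest.fixture(scope="session")
def reference():
    return TISSUES["reference"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
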