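import numpy as np
import pytest

from gliderav import Environment, ModelParams, Morphometry


@pytest.fixture
def env_const():
    """Constant seawater density, 1027 kg/m^3."""
    return Environment.constant(1027.0)


@pytest.fixture
def env_profile():
    """Southern-Ocean-like density profile, increasing with depth."""
    return Environment.from_profile(
        [0.0, 100.0, 300.0, 600.0, 800.0],
        [1026.2, 1026.8, 1027.6, 1028.6, 1029.0],
    )


@pytest.fixture
def morph300():
    """A 300 kg animal with 1.70 m girth (frontal area ~0.23 m^2)."""
    return Morphometry(mass=300.0, girth=1.70)


@pytest.fixture
def params():
    """Standard model parameters: C_d 0.03, tissue density 1037 kg/m^3."""
    return ModelParams(cd=0.03, rho_tissue=1037.0)
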