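import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nirvein.phantom import PhantomSpec, make_phantom, make_two_vein_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 96x96 three-vein phantom with all degradations on (fast unit target)."""
    spec = PhantomSpec(height=96, width=96, n_veins=2, n_hairs=2, seed=5)
    return make_phantom(spec), spec


@pytest.fixture(scope="session")
def clean_two_vein():
    """Noise-free two-vein scene: texture, hairs and sensor noise disabled."""
    spec = PhantomSpec(
        height=128,
        width=128,
        n_veins=2,
        n_hairs=0,
        texture_amplitude=0.0,
        noise_sigma=0.0,
        illumination_amplitude=0.0,
        seed=11,
    )
    return make_two_vein_phantom(spec), spec


@pytest.fixture
def step_texture_16():
    """16x16 step edge plus i.i.d. texture, fixed seed (RTV oracle scene)."""
    rng = np.random.default_rng(42)
    I = np.full((16, 16), 0.3)
    I[:, 8:] = 0.7
    return np.clip(I + 0.05 * rng.standard_normal((16, 16)), 0, 1)
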