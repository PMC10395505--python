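import numpy as np
import pytest

from shootseg.synthetic import PlantSpec, generate_plant


@pytest.fixture(scope="session")
def small_plant():
    """Noise-free 3-leaf plant with exact ground truth, shared read-only."""
    spec = PlantSpec(n_leaves=3, noise_sigma=0.0, seed=7)
    cloud, traits = generate_plant(spec)
    return cloud, traits, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
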