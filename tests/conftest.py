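import numpy as np
import pytest

from neurofuse.phantom import PhantomConfig, default_probe, default_rig, \
    generate_phantom


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def probe():
    return default_probe()


@pytest.fixture(scope="session")
def small_config():
    """A reduced phantom for fast training tests: smaller frame and pools,
    same statistical structure (3 classes, margin sites, satellites)."""
    return PhantomConfig(image_shape=(60, 64), tumor_size_mm=(3.0, 6.0),
                         n_spectra_per_specimen=600, n_pcle_healthy=8,
                         n_pcle_core=8, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_phantom(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
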