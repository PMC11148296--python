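import numpy as np
import pytest

from habitex.phantom import PhantomSpec, generate_study


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_study(default_spec):
    """One high-label phantom study at default (1% noise) settings."""
    return generate_study(default_spec, "high", seed=3)


@pytest.fixture(scope="session")
def noisefree_study():
    """Noise-free study with exact subregion fractions (no jitters)."""
    spec = PhantomSpec(noise_sigma=0.0, fraction_jitter=0.0,
                       amplitude_jitter=0.0)
    return spec, generate_study(spec, "low", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
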