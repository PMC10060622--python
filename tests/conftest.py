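import numpy as np
import pytest

from spinedvc import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 64-cube phantom shared across tests (read-only)."""
    spec = PhantomSpec(shape=(64, 64, 64), target_bvtv=0.20, noise_sd=0.0, seed=42)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_pair():
    """Zero-strain repeat pair of a 64-cube phantom (identity motion)."""
    from spinedvc import simulate_repeat_scan

    spec = PhantomSpec(shape=(64, 64, 64), target_bvtv=0.20, noise_sd=0.0, seed=7)
    vol, truth = generate_phantom(spec)
    s1 = simulate_repeat_scan(vol, truth, None, noise_sd=6.0, seed=71)
    s2 = simulate_repeat_scan(vol, truth, None, noise_sd=6.0, seed=72)
    return s1, s2, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
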