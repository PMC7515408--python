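import numpy as np
import pytest

from arifuse import GrayImage, SynthSpec, make_latent_scene, make_multifocus_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def scene():
    """A 128x128 procedural scene for fast unit tests."""
    return make_latent_scene(SynthSpec(height=128, width=128, seed=7))


@pytest.fixture(scope="session")
def multifocus():
    """The standard 256x256 multifocus experiment: (a, b, truth), sigma=3, seed 0."""
    return make_multifocus_pair(SynthSpec(seed=0, blur_sigma=3.0))


@pytest.fixture(scope="session")
def small_pair(rng):
    """Two independent 64x64 noise images quantised to 32 levels."""
    a = GrayImage((rng.integers(0, 32, (64, 64)) * 8).astype(np.int64))
    b = GrayImage((rng.integers(0, 32, (64, 64)) * 8).astype(np.int64))
    return a, b


def random_prob(rng, n):
    """A strictly positive random distribution on n bins."""
    p = rng.random(n) + 1e-3
    return p / p.sum()
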