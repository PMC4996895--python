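import numpy as np
import pytest

from canopybench import (
    LandscapeConfig,
    build_texture_stack,
    extract_samples,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 synthetic landscape shared by fast tests."""
    return generate_landscape(LandscapeConfig(grid_shape=(64, 64), seed=42))


@pytest.fixture(scope="session")
def bench_scene():
    """The full-size synthetic scene (~32k valid pixels) with textures.

    Returns (mch, textured_stack, pool) where pool holds every valid
    pixel.  Session-scoped: the benchmark-scale tests all share it.
    """
    mch, stack = generate_landscape(LandscapeConfig(seed=7))
    textured = build_texture_stack(stack)
    pool = extract_samples(textured, mch, n=None, rng_seed=11)
    return mch, textured, pool


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
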