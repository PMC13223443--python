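import numpy as np
import pytest

from chestdiff import (
    DenoiserSpec,
    PhantomParams,
    build_denoiser,
    generate_phantoms,
    make_linear_schedule,
)

# Tiny desk-scale denoiser: base 8 channels, one block per stage, attention at
# the deepest (7x7) level.  Small enough for CPU tests, deep enough to learn.
TINY_SPEC = DenoiserSpec(
    base_channels=8,
    channel_multipliers=(1, 2, 4),
    blocks_per_stage=1,
    time_embedding_dim=16,
    attention_levels=(2,),
    num_heads=2,
    image_size=28,
)


@pytest.fixture(scope="session")
def paper_schedule():
    """The T=300 linear schedule with the published beta ramp."""
    return make_linear_schedule(300, 1e-4, 0.02)


@pytest.fixture(scope="session")
def tiny_spec():
    return TINY_SPEC


@pytest.fixture(scope="session")
def tiny_model():
    return build_denoiser(TINY_SPEC, rng_seed=17)


@pytest.fixture(scope="session")
def phantoms64():
    return generate_phantoms(PhantomParams(n=64, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
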