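import pytest

from skintrack import PhantomConfig, generate_stack


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom stack + truth shared by read-only tests."""
    return generate_stack(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size geometry for tests that regenerate stacks repeatedly."""
    return PhantomConfig(
        n_px=96,
        n_planes=80,
        seed=7,
        melanin_granules_per_layer=300,
    )
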