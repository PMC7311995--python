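import pytest

from comsel import (
    BuiltinPredictor,
    FixtureSpec,
    RnaSequence,
    ZeroAccessibility,
    default_parameters,
    generate_interacting_pair,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def predictor():
    return BuiltinPredictor()


@pytest.fixture
def zero_acc():
    return ZeroAccessibility()


@pytest.fixture
def gggg_ccccc():
    return RnaSequence("a", "GGGGG"), RnaSequence("b", "CCCCC")


@pytest.fixture
def oracle_scale_fixture():
    """A seeded synthetic pair small enough for brute-force verification."""
    spec = FixtureSpec(
        site_length=6, gc_fraction=0.8, flank_length_a=3, flank_length_b=3, seed=11
    )
    return generate_interacting_pair(spec)
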