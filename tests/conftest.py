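import random

import pytest
from hypothesis import HealthCheck, settings

import mvlogic as mv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def p53():
    return mv.p53_mdm2()


def make_models(seed, count, n_range=(2, 5), max_level=2):
    rng = random.Random(seed)
    return [
        mv.random_model(rng, n_components=rng.randint(*n_range), max_level=max_level)
        for _ in range(count)
    ]


def make_boolean_models(seed, count, n_range=(2, 6)):
    rng = random.Random(seed)
    return [
        mv.random_boolean_model(rng, n_components=rng.randint(*n_range))
        for _ in range(count)
    ]


@pytest.fixture(scope="session")
def small_models():
    """Random multi-valued fixture models, small enough for state sweeps."""
    return make_models(1234, 20)


@pytest.fixture(scope="session")
def small_boolean_models():
    return make_boolean_models(99, 15)


def pattern(text):
    """Build a Pattern from a compact string, '-' or 'F' marking free entries."""
    return mv.Pattern(tuple(None if ch in "-F" else int(ch) for ch in text))


def tokens(text):
    """Whitespace-normalised token rows of a CLI output block."""
    return [line.split() for line in text.strip().splitlines()]
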