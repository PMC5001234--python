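import random
from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@lru_cache(maxsize=None)
def levenshtein_recursive(x: str, y: str) -> int:
    """Independent recursive definition of unit-cost edit distance."""
    if not x:
        return len(y)
    if not y:
        return len(x)
    return min(
        levenshtein_recursive(x[1:], y) + 1,
        levenshtein_recursive(x, y[1:]) + 1,
        levenshtein_recursive(x[1:], y[1:]) + (x[0] != y[0]),
    )


@pytest.fixture
def rand():
    return random.Random(20160818)


def random_dna(rng: random.Random, m: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(m))
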