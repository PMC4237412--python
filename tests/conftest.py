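import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from invrep import DnaSequence

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the worked 20-mer used throughout the scoring and palindrome examples
TOY = "ATCGAACGAATTCGTTAACC"


@pytest.fixture
def toy_seq() -> DnaSequence:
    return DnaSequence.from_raw("toy", TOY)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)
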