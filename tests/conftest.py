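import numpy as np
import pytest

from p53re.pattern import DEFAULT_PATTERN_SPEC, compile_pattern
from p53re.pwm import Background


@pytest.fixture(scope="session")
def default_pattern():
    return compile_pattern(DEFAULT_PATTERN_SPEC)


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160901)


def random_dna(rng, length, p=None):
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))
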