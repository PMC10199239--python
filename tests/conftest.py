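import numpy as np
import pytest

from satkit.align import InternalAligner


@pytest.fixture(scope="session")
def aligner():
    return InternalAligner()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
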