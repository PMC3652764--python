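import numpy as np
import pytest

from psse import SSSequence

#: Canonical worked-example string used throughout the docs and tests.
TOY = "CCHHHHEEEEECCCCCHHH"


@pytest.fixture
def toy() -> SSSequence:
    return SSSequence(id="toy", seq=TOY)


def random_hec_strings(n: int, seed: int, min_len: int = 1, max_len: int = 60):
    """Yield n random H/E/C strings with lengths in [min_len, max_len]."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("HEC"))
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(alphabet, size=length))
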