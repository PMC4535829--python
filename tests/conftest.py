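import numpy as np
import pytest

from asdist.synthetic import make_random_walk


@pytest.fixture
def walk20():
    return make_random_walk(20, seed=1)


@pytest.fixture
def walk_pair():
    return make_random_walk(12, seed=1), make_random_walk(12, seed=2)


def random_fragments(n, rng, lengths=(8, 40)):
    """n seeded random-walk fragments with lengths drawn from a range."""
    out = []
    for _ in range(n):
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        out.append(make_random_walk(length, seed=int(rng.integers(2**31))))
    return out
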