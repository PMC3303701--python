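import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tmcoffee.extension import ExtendedProfile
from tmcoffee.formats import Sequence
from tmcoffee.pairhmm import PairHmmParams


@pytest.fixture(scope="session")
def params() -> PairHmmParams:
    return PairHmmParams.default()


def random_profile(rng: np.random.Generator, length: int,
                   letters: str = "ACD", max_gap: float = 0.3
                   ) -> ExtendedProfile:
    """Random ExtendedProfile concentrated on a reduced alphabet."""
    from tmcoffee.formats import AA_INDEX

    freqs = np.zeros((length, 21))
    for p in range(length):
        gap = rng.uniform(0.0, max_gap)
        w = rng.random(len(letters))
        w = w / w.sum() * (1.0 - gap)
        for a, x in zip(letters, w):
            freqs[p, AA_INDEX[a]] = x
        freqs[p, 20] = gap
    query = Sequence("q", letters[0] * length)
    return ExtendedProfile(query=query, freqs=freqs,
                           support=np.ones(length, dtype=int))


def point_profile(seq: Sequence) -> ExtendedProfile:
    return ExtendedProfile.from_sequence(seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
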