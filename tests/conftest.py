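import numpy as np
import pytest

from dcltools.duplex import PenaltyScheme
from dcltools.seqio import NucSeq

BASES = "ACGT"


def random_nuc(rng: np.random.Generator, n: int, name: str = "s") -> NucSeq:
    return NucSeq(name, "".join(BASES[i] for i in rng.integers(0, 4, size=n)))


@pytest.fixture(scope="session")
def scheme() -> PenaltyScheme:
    return PenaltyScheme()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20150513)
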