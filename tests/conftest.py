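import random

import pytest

from graphmsa import ProteinSequence, ScoringParams
from graphmsa.io import AMINO_ACIDS


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20120429)


def random_protein(rng: random.Random, name: str, length: int) -> ProteinSequence:
    return ProteinSequence(
        name, "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
    )
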