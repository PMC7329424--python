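import numpy as np
import pytest

from dropsketch import Params, SequenceRecord, Taxonomy
from dropsketch.reference_db import build_database

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def default_params() -> Params:
    return Params()  # k=16, s=16, w=56, t=41, r=3, threshold=28


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_reference(rng):
    """Three genes; geneA has two isoforms sharing their first half."""
    rng = np.random.default_rng(42)
    tax = Taxonomy()
    a1 = random_seq(rng, 400)
    a2 = a1[:200] + random_seq(rng, 200)
    b = random_seq(rng, 300)
    c = random_seq(rng, 250)
    records = [
        SequenceRecord("txA1", a1),
        SequenceRecord("txA2", a2),
        SequenceRecord("txB", b),
        SequenceRecord("txC", c),
    ]
    for tx, gene in [("txA1", "geneA"), ("txA2", "geneA"), ("txB", "geneB"), ("txC", "geneC")]:
        tax.add(tx, gene)
    return records, tax


@pytest.fixture
def toy_db(toy_reference, default_params):
    records, tax = toy_reference
    return build_database(iter(records), tax, default_params)
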