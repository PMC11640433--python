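import numpy as np
import pytest

from groupnet import GroupByIndividualMatrix, IndividualRecord


@pytest.fixture
def abc_roster():
    return [
        IndividualRecord("A", "capuchin", "F", "G"),
        IndividualRecord("B", "capuchin", "M", "G"),
        IndividualRecord("C", "squirrel_monkey", "F", "G"),
    ]


@pytest.fixture
def gbi_factory():
    """Build a GBI from party sets, e.g. [{'A','B'}, {'A'}] over given ids."""

    def make(parties, ids, roster=None, row_parties=None):
        matrix = np.zeros((len(parties), len(ids)), dtype=np.int8)
        for p, party in enumerate(parties):
            for ident in party:
                matrix[p, ids.index(ident)] = 1
        period_ids = [f"p{p + 1}" for p in range(len(parties))]
        return GroupByIndividualMatrix(
            matrix, period_ids, ids, roster=roster, row_parties=row_parties
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
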