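import numpy as np
import pytest

from tcrmhc import default_interaction_matrix
from tcrmhc.repertoire import SequenceRecord


@pytest.fixture(scope="session")
def matrix():
    return default_interaction_matrix()


def make_record(id, segments, family="TRAV", functionality="productive"):
    return SequenceRecord(
        id=id,
        family=family,
        functionality=functionality,
        sequence="".join(segments.values()),
        segments=dict(segments),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
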