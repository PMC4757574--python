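import numpy as np
import pytest

from cleavemap import Reference, ReferenceSet, SequencedRead


@pytest.fixture
def rng():
    return np.random.default_rng(20160217)


@pytest.fixture
def small_refs():
    """Two short DNA references with a shared poly(A) suffix."""
    return ReferenceSet(
        [
            Reference("r1", "GGGACGTTACGATACCAGTT" + "A" * 20),
            Reference("r2", "GGGTTCAGGACATCGGTCCA" + "A" * 20),
        ],
        alphabet="DNA",
    )


def make_read(sequence, quality=40, read_id="r", mate=0):
    if isinstance(quality, int):
        scores = [quality] * len(sequence)
    else:
        scores = list(quality)
    return SequencedRead.from_scores(read_id, sequence, scores, mate)
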