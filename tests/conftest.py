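import numpy as np
import pytest

from ecnet.datatypes import ExpressionMatrix, Strand, TranscriptID


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, ids=None, samples=None, strands=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if ids is None:
        ids = [f"g{i}" for i in range(n)]
    if strands is None:
        strands = [Strand.SENSE] * n
    transcripts = [TranscriptID(b, s) for b, s in zip(ids, strands)]
    if samples is None:
        samples = [f"s{j}" for j in range(p)]
    return ExpressionMatrix(transcripts, samples, values)


@pytest.fixture
def random_matrix(rng):
    def factory(n=10, p=20):
        return make_matrix(rng.normal(size=(n, p)))

    return factory
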