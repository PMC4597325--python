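import numpy as np
import pytest

from rpcselect import Corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Three short documents over a 4-word vocabulary."""
    return Corpus(
        documents=[np.array([0, 1, 2]), np.array([1, 1, 3]), np.array([0, 3])],
        vocabulary=["apple", "banana", "cherry", "date"],
        doc_ids=["d1", "d2", "d3"],
    )


@pytest.fixture
def single_word_corpus() -> Corpus:
    """V=1: one word repeated across two documents."""
    return Corpus(
        documents=[np.array([0, 0, 0]), np.array([0, 0])],
        vocabulary=["only"],
        doc_ids=["d1", "d2"],
    )
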