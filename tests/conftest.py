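import numpy as np
import pytest

from methylsite import ProteinRecord, SiteAnnotation
from methylsite.datasets import extract_window


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_protein():
    # K at 2 and 7 (7 annotated), R at 4
    return ProteinRecord(
        id="p1",
        sequence="MKARAAKLLS",
        sites=[SiteAnnotation(7, "K", frozenset({"mono"}))],
    )


@pytest.fixture
def window_of():
    def make(text):
        assert len(text) % 2 == 1
        return extract_window(text, (len(text) + 1) // 2, len(text))

    return make
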