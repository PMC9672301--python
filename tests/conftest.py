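import numpy as np
import pytest

from vocalscales.pitch_extraction import CentAnnotationSet
from vocalscales.segmentation import segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cluster_cents(rng):
    """1000 annotations in two clusters at 0 and 200 cents, +-20 scatter."""
    a = rng.uniform(-20, 20, 500)
    b = 200 + rng.uniform(-20, 20, 500)
    return np.concatenate([a, b])


@pytest.fixture
def five_cluster_cents(rng):
    """Five clusters at 0/200/350/500/700 cents with +-30 scatter."""
    centers = [0, 200, 350, 500, 700]
    return np.concatenate([c + rng.uniform(-30, 30, 200) for c in centers])


@pytest.fixture
def simple_pcs():
    """A tiny two-class segmentation: means 100 and 300, tonic below."""
    vals = np.concatenate([100 + np.linspace(-10, 10, 21), 300 + np.linspace(-15, 15, 21)])
    return segment(CentAnnotationSet(cents=vals))
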