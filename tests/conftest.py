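import numpy as np
import pytest

from hrvrisk.io_preprocess import NNSeries


def make_nn(values, **kw) -> NNSeries:
    return NNSeries(nn=np.asarray(values, dtype=float), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_series():
    return make_nn([800.0] * 400)
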