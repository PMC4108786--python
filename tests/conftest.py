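import numpy as np
import pytest

from slgraph.io_layout import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_epochs(rng):
    """2 subjects x 2 conditions x 1 session x 2 epochs of 3 channels."""
    data = {
        (s, c, 0, e): rng.standard_normal((3, 64))
        for s in ("S01", "S02")
        for c in ("NS", "TSD")
        for e in (0, 1)
    }
    return EpochSet(data=data, fs=32.0, channel_names=["a", "b", "c"])
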