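import numpy as np
import pytest

from cpdid.preprocess import QuarterlySeries


def make_series(y, O=None, start_year=2001, group="g"):
    y = np.asarray(y, dtype=int)
    n = len(y)
    t = np.arange(1, n + 1)
    if O is None:
        O = np.ones(n)
    return QuarterlySeries(
        t=t,
        year=start_year + (t - 1) // 4,
        quarter=(t - 1) % 4 + 1,
        y=y,
        O=np.asarray(O, dtype=float),
        group=group,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
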