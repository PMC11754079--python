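import numpy as np
import pytest

from eiphys import synthetic


@pytest.fixture
def mini_sweep():
    """Standard mini sweep: 2 Hz, 25 pA, sigma 1.5 pA, 120 s, seed 1."""
    return synthetic.gen_mini_sweep(seed=1)


@pytest.fixture
def short_psg():
    """One 10-minute synthetic day (150 epochs) of polysomnography."""
    return synthetic.gen_polysomnography(seed=0, epochs_per_day=150)


@pytest.fixture
def imaging_truth():
    return synthetic.make_imaging_truth(shape=(16, 16))


def assert_close(a, b, rtol=0.0, atol=0.0):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
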