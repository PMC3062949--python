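import numpy as np
import pytest

import tubeness as tb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Smooth-ish random volume (white noise lightly blurred)."""
    data = rng.normal(size=(32, 32, 32))
    return tb.gaussian_smooth(tb.Volume(data), tb.GaussianProbe(1.0))


@pytest.fixture
def straight_tube():
    """Unit-amplitude Gaussian-profile tube along z, sigma_obj = 3."""
    n = 48
    tube = tb.TubeSpec(
        centerline=[(0, n / 2, n / 2), (n - 1, n / 2, n / 2)],
        profile="gaussian", sigma_obj=3.0, amplitude=1.0,
    )
    return tb.make_tube(tube, (n, n, n))
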