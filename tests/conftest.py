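import numpy as np
import pytest

from wavefbn import (
    RoiTimeSeries,
    WaveletConfig,
    fcwt_decompose,
    resample_to_unit_rate,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_decomposition():
    """Wavelet decomposition of a 4-ROI white-noise subject, unit rate."""
    data = np.random.default_rng(7).standard_normal((240, 4))
    ts = RoiTimeSeries("noise", data, tr=1.0)
    return fcwt_decompose(resample_to_unit_rate(ts), WaveletConfig())


def complex_pair(seed: int, n: int = 60) -> tuple[np.ndarray, np.ndarray]:
    r = np.random.default_rng(seed)
    x = r.standard_normal(n) + 1j * r.standard_normal(n)
    y = r.standard_normal(n) + 1j * r.standard_normal(n)
    return x, y
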