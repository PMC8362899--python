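import numpy as np
import pytest

from seedlingvision.preprocess import IntensityHistogram


def make_smooth_histogram(rng: np.random.Generator) -> IntensityHistogram:
    """Random smooth multi-modal 256-bin histogram (2-4 Gaussian modes)."""
    x = np.arange(256)
    p = np.full(256, 1e-4)
    for _ in range(int(rng.integers(2, 5))):
        mu = rng.uniform(10, 245)
        s = rng.uniform(5, 40)
        a = rng.uniform(0.5, 2.0)
        p += a * np.exp(-(((x - mu) / s) ** 2) / 2)
    p /= p.sum()
    return IntensityHistogram(probs=p, total_pixels=100_000)


@pytest.fixture
def smooth_histograms():
    rng = np.random.default_rng(12345)
    return [make_smooth_histogram(rng) for _ in range(5)]
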