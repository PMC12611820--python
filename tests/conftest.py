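import numpy as np
import pytest

from entroflow import DensityGrid


def gaussian_pdf(x, mean=0.0, sd=1.0):
    return np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def mixture_pdf(x, means, sds, weights):
    out = np.zeros_like(np.asarray(x, float))
    for m, s, w in zip(means, sds, weights):
        out += w * gaussian_pdf(x, m, s)
    return out


def ar1(rng, T, rho=0.8, sd=1.0):
    """A stationary AR(1) series (autocorrelated null signal)."""
    x = np.empty(T)
    x[0] = rng.normal(0, sd / np.sqrt(1 - rho**2))
    eps = rng.normal(0, sd, T)
    for i in range(1, T):
        x[i] = rho * x[i - 1] + eps[i]
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_normal_grid():
    return DensityGrid.gaussian(0.0, 1.0, n=2048, span_sd=8.0)


@pytest.fixture
def skewed_grid():
    """A visibly asymmetric density (two-component Gaussian mixture)."""
    x = np.linspace(-8, 12, 2048)
    return DensityGrid.from_values(
        x, mixture_pdf(x, [-0.5, 3.0], [0.8, 2.0], [0.7, 0.3])
    )
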