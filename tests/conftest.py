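import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def quadrature_cdf(log_kernel, lo, hi, n=200001):
    """Numerically normalised CDF of an unnormalised density on (lo, hi).

    Returns a callable cdf(x) built from a dense trapezoid grid; used as the
    independent oracle for full-conditional samplers.
    """
    xs = np.linspace(lo, hi, n)
    lk = log_kernel(xs)
    lk = np.where(np.isfinite(lk), lk, -np.inf)
    pdf = np.exp(lk - lk.max())
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5
                                           * np.diff(xs))])
    cdf /= cdf[-1]

    def _cdf(v):
        return np.interp(v, xs, cdf)

    return _cdf
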