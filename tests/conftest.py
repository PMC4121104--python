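import numpy as np
import pytest
from scipy.optimize import brentq

from circobs import InputSignal, ModelParameters, simulate


def bracket_root(f, lo, hi, n=400):
    """Root of a continuous scalar function on [lo, hi] by sign-change scan
    plus Brent refinement.  Handles non-monotone (e.g. unimodal Hill slope)
    profiles where a plain two-endpoint bracket fails; a root is guaranteed
    by the mean value theorem in the uses below."""
    xs = np.linspace(lo, hi, n)
    vals = np.array([f(x) for x in xs])
    sign = np.sign(vals)
    for i in range(n - 1):
        if sign[i] == 0:
            return xs[i]
        if sign[i] * sign[i + 1] < 0:
            return brentq(f, xs[i], xs[i + 1], xtol=1e-14)
    return xs[int(np.argmin(np.abs(vals)))]


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def unforced_trajectory(params):
    """One long free-running run shared by period/bound/box tests."""
    return simulate(params, InputSignal.zero(), np.ones(5), (0.0, 500.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
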