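import numpy as np
import pytest

from gapcnn.network import init_params, tiny_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net():
    """A dropout-free 8x8-input network plus params, small enough for
    full finite-difference sweeps."""
    spec = tiny_spec(input_size=8, channels=1, widths=(3, 4))
    return spec, init_params(spec, seed=1)


def central_diff(f, x, h=1e-6):
    """Central finite difference of a scalar function of an array,
    element by element."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        orig = x[ix]
        x[ix] = orig + h
        fp = f(x)
        x[ix] = orig - h
        fm = f(x)
        x[ix] = orig
        g[ix] = (fp - fm) / (2 * h)
    return g


def max_rel_err(a, b, floor=1e-8):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    return float(np.max(np.abs(a - b) / denom))
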