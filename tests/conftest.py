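import numpy as np
import pytest

from reefdet.autograd import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar-valued numpy function."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_grad(op, x0: np.ndarray, rtol: float = 1e-5, atol: float = 1e-7):
    """Compare autograd gradient of ``sum(op(x))`` with finite differences."""
    x0 = x0.astype(np.float64)
    t = Tensor(x0, requires_grad=True)
    out = op(t)
    out.sum().backward()
    analytic = t.grad

    def scalar(x):
        return float(op(Tensor(x)).sum().data)

    numeric = numeric_grad(scalar, x0.copy())
    np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)


@pytest.fixture
def grad_checker():
    return check_grad
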