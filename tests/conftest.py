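import numpy as np
import pytest

from udrnet import (DeformSpec, NetworkConfig, PhantomSpec, RegistrationModel,
                    make_pair)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """3-level network small enough for 16^3 volumes in unit tests."""
    return NetworkConfig(levels=3, enc_channels=(2, 4, 4), dec_channels=(4, 4, 2),
                         prehead_channels=4)


@pytest.fixture(scope="session")
def tiny_pair():
    """One 16^3 synthetic pair with a recoverable ground-truth field."""
    return make_pair(PhantomSpec(shape=(16, 16, 16), seed=7),
                     DeformSpec(max_displacement=2.0, smoothness_sigma=4.0, seed=7))


@pytest.fixture
def tiny_model(tiny_net_cfg):
    return RegistrationModel(tiny_net_cfg)


def numerical_gradient(f, x, eps=1e-3):
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g
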