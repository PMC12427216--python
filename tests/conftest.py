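import numpy as np
import pytest

from pigletdet.config import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete detector configuration."""
    return ModelConfig(backbone_widths=(12, 24, 36, 48), local_width=24,
                       fused_width=24, ifm_blocks=1, input_size=128, seed=7)


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar f() with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
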