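import numpy as np
import pytest

from ginsengdet import nn
from ginsengdet.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def numerical_grad(fn, x, eps=1e-3):
    """Central-difference gradient of scalar fn() w.r.t. tensor x.data."""
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x.data[i]
        x.data[i] = old + eps
        fp = fn()
        x.data[i] = old - eps
        fm = fn()
        x.data[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_close(build, tensors, rtol=2e-2, seed=0, eps=1e-5):
    """Check autodiff grads of build() output against central differences.

    Tensors are promoted to float64 so the finite differences are not
    limited by single-precision loss resolution."""
    for t in tensors:
        t.data = t.data.astype(np.float64)
    w = np.random.default_rng(seed).normal(0, 1, build().shape)
    for t in tensors:
        t.grad = None
    out = build()
    (out * w).sum().backward()
    for t in tensors:
        ng = numerical_grad(lambda: float((build().data * w).sum()), t,
                            eps=eps)
        scale = max(np.abs(ng).max(), np.abs(t.grad).max(), 1e-8)
        assert t.grad is not None
        assert np.abs(ng - t.grad).max() / scale < rtol


@pytest.fixture(scope="session")
def toy_scenes_64():
    """Small easy scenes (large fruit, light occlusion) for toy training."""
    import warnings

    spec = lambda i: SceneSpec(img_size=64, n_plants=2,
                               occlusion_fraction=0.05,
                               berry_radius=(25, 45), cluster_radius=50,
                               seed=i)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [generate_scene(spec(i)) for i in range(110)]


@pytest.fixture(autouse=True)
def _fixed_init_seed():
    nn.seed_init(0)
    yield
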