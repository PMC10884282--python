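import numpy as np
import pytest

from polypdet.synthetic import SceneParams, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight deterministic small scenes with labels, for data-pipeline tests."""
    out = []
    for i in range(8):
        p = SceneParams(size=96, seed=100 + i, polyp_count=(1, 2))
        out.append(generate_scene(p))
    return out


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of one array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        hi = f()
        x[i] -= 2 * eps
        lo = f()
        x[i] += eps
        g[i] = (hi - lo) / (2 * eps)
    return g
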