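import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def circle():
    """A fine circular polygon of radius 50 centred at the origin."""
    ang = 2 * np.pi * np.arange(256) / 256
    return np.column_stack([50 * np.cos(ang), 50 * np.sin(ang)])


def smooth_random_map(n_markers=100, n_cols=40, n_bumps=8, amplitude=0.8, seed=0):
    """Band-limited random morphodynamic map: sum of circular space-time
    Gaussian bumps, used as ground truth for round-trip tests."""
    rng = np.random.default_rng(seed)
    values = np.zeros((n_markers, n_cols))
    rows = np.arange(n_markers)
    for _ in range(n_bumps):
        r0 = rng.uniform(0, n_markers)
        t0 = rng.uniform(0, n_cols)
        sr = rng.uniform(4, 8)
        st = rng.uniform(3, 6)
        amp = rng.uniform(-amplitude, amplitude)
        d = np.abs(rows - r0)
        d = np.minimum(d, n_markers - d)
        values += amp * np.exp(-0.5 * (d / sr) ** 2)[:, None] * np.exp(
            -0.5 * ((np.arange(n_cols) - t0) / st) ** 2
        )[None, :]
    return values
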