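import numpy as np
import pytest

from smtrace import simkit


@pytest.fixture
def noiseless_photo():
    return simkit.PhotophysicsParams.noiseless(3000.0)


@pytest.fixture
def default_photo():
    return simkit.PhotophysicsParams(
        total_intensity=3000.0,
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.0,
        background_mean=200.0,
        background_sd=30.0,
        excess_noise_factor=2.0,
    )


@pytest.fixture
def two_state_scheme():
    """Symmetric open/compact exchange, 1.69 s relaxation time."""
    k = 1.0 / (2 * 1.69)
    return simkit.KineticScheme.two_state(0.1, 0.5, k, k)


def grid_positions(n, lo=10, hi=62, spacing=12, jitter=2.0, seed=0):
    """Well-separated spot positions for rendering fixtures."""
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(lo, hi, spacing), np.arange(lo, hi, spacing))
    pos = np.column_stack([xs.ravel(), ys.ravel()])[:n].astype(float)
    return pos + rng.uniform(-jitter, jitter, pos.shape)
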