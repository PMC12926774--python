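import numpy as np
import pytest

from spinalcompcor import (PhantomConfig, build_noise_roi, simulate_phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Phantom with planted components and thermal noise only."""
    cfg = PhantomConfig(n_components=5, seed=11)
    vol, masks, truth = simulate_phantom(cfg)
    return vol, masks, truth


@pytest.fixture(scope="session")
def noise_roi_mask(quiet_phantom):
    _, masks, _ = quiet_phantom
    return build_noise_roi(masks["cord_csf"])


def ar1_series(rng, T, rho=0.6, n=1):
    """Autocorrelated test series; returns (n, T) or (T,)."""
    x = np.empty((n, T))
    x[:, 0] = rng.standard_normal(n)
    eps = rng.standard_normal((n, T))
    for t in range(1, T):
        x[:, t] = rho * x[:, t - 1] + eps[:, t]
    return x[0] if n == 1 else x
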