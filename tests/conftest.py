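import numpy as np
import pytest

from lamsans import InstrumentConfig, ScatteringCurve, nallet_intensity


@pytest.fixture
def q200():
    """200 log-spaced points over the instrument span (Å⁻¹)."""
    return np.geomspace(0.002, 0.4, 200)


@pytest.fixture
def instrument():
    return InstrumentConfig()


@pytest.fixture
def unsmeared():
    """Instrument with delta-function resolution (exact model on grid)."""
    return InstrumentConfig(resolution_sigmas=(0.0, 0.0, 0.0))


def make_curve(params, q, sigma_rel=None, seed=0):
    """Exact (unsmeared) lineshape curve, optionally with seeded noise."""
    clean = nallet_intensity(q, params)
    if sigma_rel is None:
        return ScatteringCurve(q, clean)
    rng = np.random.default_rng(seed)
    sigma = sigma_rel * clean
    noisy = np.maximum(clean + rng.normal(0.0, 1.0, q.size) * sigma, 0.0)
    return ScatteringCurve(q, noisy, sigma)
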