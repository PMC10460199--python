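import dataclasses

import numpy as np
import pytest

from aortaflow import JetParams, analyze_series, simulate_velocity_series


@pytest.fixture(scope="session")
def laminar_params():
    """Centred jet, no retro, no noise — the null acquisition."""
    return JetParams()


@pytest.fixture(scope="session")
def laminar_sim(laminar_params):
    return simulate_velocity_series(laminar_params)


@pytest.fixture(scope="session")
def eccentric_sim():
    """Static jet displaced 0.20 x D_eq, no noise."""
    p = JetParams(offset_fraction=0.20)
    return simulate_velocity_series(p)


@pytest.fixture(scope="session")
def laminar_analysis(laminar_sim):
    series, masks, gt = laminar_sim
    metrics, frames, lm = analyze_series(series, masks, bsa=1.72)
    return metrics, frames, lm, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def disc_mask(grid: int, radius_px: float, center=None) -> np.ndarray:
    """Rasterised disc used by several oracle tests."""
    if center is None:
        center = ((grid - 1) / 2.0, (grid - 1) / 2.0)
    yy, xx = np.mgrid[0:grid, 0:grid]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
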