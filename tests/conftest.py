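import numpy as np
import pytest

from mpsquant import PatternParams, SimulationConfig, simulate, solve_background_for_sbr


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def mps_config():
    """Simulation config of a structured neurite tile (phase 1.0, 30 deg)."""
    return SimulationConfig(pattern=PatternParams(phi=1.0), theta_true=30.0, seed=11)


@pytest.fixture(scope="session")
def sim_tile_sbr8(mps_config):
    """One seeded simulated tile at SBR target 8."""
    solved = solve_background_for_sbr(mps_config, 8.0)
    return simulate(solved)


def make_band(shape, angle_deg, width_px, length_px=None):
    """Binary band through the tile center at a given angle (test geometry).

    The angle follows the package convention: counter-clockwise from the
    column axis, y along rows.
    """
    rows, cols = shape
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    t = np.deg2rad(angle_deg)
    s = c * np.cos(t) + r * np.sin(t)
    v = -c * np.sin(t) + r * np.cos(t)
    band = np.abs(v) <= width_px / 2.0
    if length_px is not None:
        band &= np.abs(s) <= length_px / 2.0
    return band
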