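import numpy as np
import pytest
from hypothesis import settings

from iptsl.config import Numerics, ScenarioConfig
from iptsl.flow import solve_flow
from iptsl.geometry import build_domain, grid_from_edges

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def default_grid(default_config):
    return build_domain(default_config)


@pytest.fixture(scope="session")
def default_flow(default_grid, default_config):
    return solve_flow(default_grid, default_config)


@pytest.fixture(scope="session")
def small_config():
    """R = 2 mm scenario with a reduced polar resolution for quick runs."""
    return ScenarioConfig(tumor_radius_R=2e-3, numerics=Numerics(n_theta=8))


def fine_surface_grid(R=10e-3, Rn=5e-3, n_theta=4, dx_fine=2e-6, band=4e-4, n_coarse=40):
    """Hand-built mesh with very fine surface resolution for boundary-layer tests."""
    fine = np.arange(R - band, R + dx_fine / 2, dx_fine)
    coarse = np.linspace(0.0, R - band, n_coarse + 1)
    r_edges = np.unique(np.concatenate([coarse, fine, [Rn]]))
    theta_edges = np.linspace(0.0, np.pi, n_theta + 1)
    return grid_from_edges(r_edges, theta_edges, R, Rn)


def line_grid(n=20, R=1e-3, Rn=0.5e-3):
    """Tiny 1D (single polar cell) mesh for matrix-exponential oracle tests."""
    r_edges = np.linspace(0.0, R, n + 1)
    theta_edges = np.array([0.0, np.pi])
    return grid_from_edges(r_edges, theta_edges, R, Rn)
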