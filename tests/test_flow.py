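"""Interstitial flow: Starling source, Darcy solver vs the closed form."""

import numpy as np
import pytest

from iptsl.config import ScenarioConfig, TissueParams
from iptsl.flow import radial_profile, solve_flow, starling_source
from iptsl.oracles import analytic_flow


def test_starling_source_values(default_config):
    # flux vanishes at the effective filtration pressure
    assert starling_source(1470.0, default_config) == pytest.approx(0.0, abs=1e-18)
    # direct evaluation at zero interstitial pressure
    assert starling_source(0.0, default_config) == pytest.approx(6.174e-4, rel=1e-6)
    cfg = ScenarioConfig(tissue=TissueParams(sigma_s=0.0))
    assert starling_source(cfg.tissue.P_B, cfg) == pytest.approx(0.0, abs=1e-18)
    # may be negative above P_e
    assert starling_source(2000.0, default_config) < 0.0


def test_solver_matches_two_region_closed_form(default_grid, default_flow, default_config):
    an = analytic_flow(10e-3, 5e-3, default_config)
    rc = default_grid.r_centers[: default_grid.i_surface]
    for j in range(default_grid.nt):
        err = np.max(np.abs(default_flow.P[:, j] - an.pressure(rc))) / an.P_e
        assert err < 0.01
    assert an.ode_residual() < 1e-6


def test_flow_diagnostics(default_flow):
    d = default_flow.diagnostics
    # pressure plateau capped by the effective filtration pressure
    assert d["max_ifp_Pa"] <= 1470.0 + 1e-6
    assert d["max_ifp_Pa"] == pytest.approx(1470.0, rel=1e-3)
    # velocity maximal on the tumor surface, zero at the center
    assert d["max_ifv_m_s"] == pytest.approx(1.606e-7, rel=0.02)
    assert np.abs(default_flow.v_r[1]).max() < 1e-12
    inner = np.abs(default_flow.v_r[1:-1]).max()
    assert d["max_ifv_m_s"] >= inner
    assert d["mass_balance_rel"] < 0.005
    assert default_flow.P.min() >= -1e-9


def test_scaling_invariance_alpha_squared(default_grid):
    """P_i depends on L_P(S/V)/kappa only; scaling kappa and L_P together
    leaves the pressure unchanged."""
    base = solve_flow(default_grid, ScenarioConfig())
    scaled = ScenarioConfig(tissue=TissueParams(kappa=3e-13, L_P=2.10e-10))
    other = solve_flow(default_grid, scaled)
    assert np.allclose(base.P, other.P, rtol=1e-8, atol=1e-8)
    # velocities scale with kappa
    assert np.allclose(other.v_r, 10.0 * base.v_r, rtol=1e-8)


def test_radial_profile(default_grid, default_flow):
    const = np.ones((default_grid.i_surface, default_grid.nt))
    d, v = radial_profile(default_grid, const)
    assert np.all(np.diff(d) > 0)
    assert np.allclose(v, 1.0)
    assert d[-1] <= default_grid.tumor_radius
    d, p = radial_profile(default_grid, default_flow.P)
    # pressure decreases from the central plateau to ~0 at the surface
    assert p[0] < 50.0
    assert p[-1] == pytest.approx(1470.0, rel=1e-3)
    assert np.all(np.diff(p) >= -1e-9)
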