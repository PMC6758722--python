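"""Pennes solver, Arrhenius damage, PI controller."""

import numpy as np
import pytest

from iptsl.config import Numerics, RegionThermal, ScenarioConfig, ThermalParams
from iptsl.acoustics import bowl_field
from iptsl.bioheat import PIController, arrhenius_DP, solve_bioheat
from iptsl.geometry import build_domain
from iptsl.oracles import heat_kernel_gaussian


def test_arrhenius_reference_values():
    Af, dE = 1.98e106, 6.67e5
    t = np.array([0.0, 3600.0])
    assert arrhenius_DP(t, np.array([[37.0], [37.0]]), Af, dE)[0] == pytest.approx(0.997, abs=2e-3)
    t = np.array([0.0, 600.0])
    assert arrhenius_DP(t, np.array([[43.0], [43.0]]), Af, dE)[0] == pytest.approx(0.93, abs=5e-3)
    assert arrhenius_DP(np.array([0.0]), np.array([[43.0]]), Af, dE) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        arrhenius_DP(np.array([0.0, 2.0, 1.0]), np.zeros((3, 1)), Af, dE)


def test_pi_controller_contract():
    ctrl = PIController(T_set=43.0, K_p=0.2, K_i=0.01)
    assert ctrl.update(43.0, 1.0) == 0.0
    ctrl = PIController(T_set=43.0)
    assert ctrl.update(38.0, 0.0) == pytest.approx(1.0)   # 0.2 * 5
    # persistent overshoot: output clamps at zero, never negative,
    # and the accumulator freezes while clamped (anti-windup)
    ctrl = PIController(T_set=43.0)
    for _ in range(50):
        assert ctrl.update(48.0, 1.0) == 0.0
    assert ctrl.integral == 0.0
    assert ctrl.update(38.0, 1.0) > 0.0
    with pytest.raises(ValueError):
        PIController(43.0, K_p=-0.1)


def test_no_source_stays_at_body_temperature(small_config):
    grid = build_domain(small_config)
    ts = solve_bioheat(grid, np.zeros((grid.nr, grid.nt)), small_config, duration=60.0)
    assert np.allclose(ts.T_snapshots[-1], 37.0, atol=1e-9)


def test_transient_conduction_matches_heat_kernel():
    """Gaussian hot spot relaxing by pure conduction vs the free-space kernel."""
    th = ThermalParams(tumor=RegionThermal(1000.0, 3800.0, 0.552, 0.0),
                       normal=RegionThermal(1000.0, 3800.0, 0.552, 0.0))
    cfg = ScenarioConfig(mode="conventional", thermal=th,
                         numerics=Numerics(t_ramp=0.0, t_mid=0.0, dt_thermal=0.5))
    grid = build_domain(cfg)
    sigma0, dT0, t_end = 2e-3, 5.0, 60.0
    rc = grid.r_centers[:, None] * np.ones((1, grid.nt))
    T0 = 37.0 + dT0 * np.exp(-rc**2 / (2 * sigma0**2))
    ts = solve_bioheat(grid, np.zeros_like(T0), cfg, duration=t_end, T_init=T0,
                       control=False, damage=False, perfusion=False)
    D = 0.552 / (1000.0 * 3800.0)
    T_ref = 37.0 + heat_kernel_gaussian(rc, t_end, D, sigma0, dT0)
    err = np.max(np.abs(ts.T_snapshots[-1] - T_ref)) / dT0
    assert err < 0.02


@pytest.fixture(scope="module")
def controlled_run(default_grid):
    cfg = ScenarioConfig(mode="tsl")
    fld = bowl_field(cfg, default_grid, f=1.0e6, check_convergence=False)
    return solve_bioheat(default_grid, fld.q, cfg, duration=900.0), cfg


def test_controlled_heating(controlled_run):
    ts, cfg = controlled_run
    after_ramp = ts.probe_times > 300.0
    # held at the set point with bounded overshoot; never below body temperature
    assert np.all(ts.probe_T[after_ramp] <= cfg.thermal.T_set + 0.5)
    assert ts.probe_T[-1] == pytest.approx(cfg.thermal.T_set, abs=0.05)
    assert ts.T_snapshots[-1].min() >= 37.0 - 1e-9
    assert np.all(ts.K_HIFU >= 0.0)
    # perfusion reduction is monotone in time and stays in (0, 1]
    assert np.all(np.diff(ts.min_DP) <= 1e-15)
    assert 0.0 < ts.min_DP[-1] <= 1.0
    assert np.allclose(ts.D_P, np.exp(-(-np.log(ts.D_P))))
    # discrete energy balance closes
    assert ts.diagnostics["energy_residual_max"] < 0.01


def test_damage_negligible_at_mild_temperatures(default_grid):
    """Near body temperature an hour of heating barely touches the perfusion."""
    cfg = ScenarioConfig(mode="tsl")
    T_hist = np.full((2, 1), 38.0)
    dp = arrhenius_DP(np.array([0.0, 3600.0]), T_hist, cfg.thermal.A_f, cfg.thermal.dE)
    assert dp[0] > 0.99
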