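"""Hindered-transport coefficients: Stokes-Einstein, fiber matrix, pore model."""

import math

import pytest
from hypothesis import given, strategies as st

from iptsl.config import ScenarioConfig
from iptsl.hindrance import (fiber_matrix_DL, liposome_coefficients, pore_area_factor,
                             pore_model, renkin_hindrance, stokes_einstein_D0)


def test_stokes_einstein():
    D = stokes_einstein_D0(100e-9, T=310.15, viscosity=7.0e-4)
    assert D == pytest.approx(6.49e-12, rel=0.01)
    assert stokes_einstein_D0(200e-9) == pytest.approx(stokes_einstein_D0(100e-9) / 2)
    assert stokes_einstein_D0(5e-9) / stokes_einstein_D0(200e-9) == pytest.approx(40.0)
    with pytest.raises(ValueError):
        stokes_einstein_D0(-1e-9)


def test_fiber_matrix():
    D0 = 1e-11
    assert fiber_matrix_DL(D0, 50e-9, 200e-9, 0.0) == D0
    assert fiber_matrix_DL(D0, 0.0, 200e-9, 0.04) == pytest.approx(D0 * math.exp(-0.2))
    assert fiber_matrix_DL(D0, 100e-9, 200e-9, 0.05) < fiber_matrix_DL(D0, 2.5e-9, 200e-9, 0.05)
    with pytest.raises(ValueError):
        fiber_matrix_DL(D0, -1.0, 200e-9, 0.05)
    with pytest.raises(ValueError):
        fiber_matrix_DL(D0, 1e-9, 200e-9, 1.5)


def test_renkin_polynomial_value():
    # direct evaluation at lambda = 1/2
    assert renkin_hindrance(0.5) == pytest.approx(0.0449, abs=2e-4)
    assert renkin_hindrance(0.0) == 1.0
    assert renkin_hindrance(1.0) == 0.0


def test_pore_model_limits():
    P, s = pore_model(200e-9, 200e-9, 5e-6, 1e-11, gamma=0.03)   # lambda = 1
    assert P == 0.0 and s == 1.0
    P, s = pore_model(0.0, 200e-9, 5e-6, 1e-11, gamma=0.03)      # lambda = 0
    assert s == 0.0 and P == pytest.approx(0.03 * 1e-11 / 5e-6)
    with pytest.raises(ValueError):
        pore_model(1e-9, -1.0, 5e-6, 1e-11, gamma=0.03)


def test_calibration_reproduces_free_drug_permeability():
    cfg = ScenarioConfig(mode="tsl")
    t, tr = cfg.tissue, cfg.transport
    D0_dox = stokes_einstein_D0(tr.dox_diameter, viscosity=tr.viscosity)
    gamma = pore_area_factor(tr.P_dox, D0_dox, tr.dox_diameter / 2, t.r_p, t.delta_wall)
    P_eff, _ = pore_model(tr.dox_diameter / 2, t.r_p, t.delta_wall, D0_dox, gamma)
    assert P_eff == pytest.approx(tr.P_dox, rel=1e-12)


def test_size_selectivity_of_vessel_wall():
    """A 100 nm TSL leaks across 200 nm pores; a 200 nm TSL cannot."""
    leaky = liposome_coefficients(ScenarioConfig(mode="tsl", tsl_diameter=100e-9))
    sealed = liposome_coefficients(ScenarioConfig(mode="tsl", tsl_diameter=400e-9))
    assert leaky.P_eff > 0.0 and leaky.sigma_f < 1.0
    assert sealed.P_eff == 0.0 and sealed.sigma_f == 1.0
    assert leaky.D_L <= leaky.D0


@given(st.floats(min_value=1e-9, max_value=290e-9), st.floats(min_value=1e-9, max_value=290e-9))
def test_monotonicity_in_particle_size(d1, d2):
    """All coefficients are monotone in particle diameter."""
    a, b = sorted((d1, d2))
    ca = liposome_coefficients(ScenarioConfig(mode="tsl", tsl_diameter=a))
    cb = liposome_coefficients(ScenarioConfig(mode="tsl", tsl_diameter=b))
    assert cb.D0 <= ca.D0 * (1 + 1e-12)
    assert cb.D_L <= ca.D_L * (1 + 1e-12)
    assert cb.P_eff <= ca.P_eff + 1e-18
    assert cb.sigma_f >= ca.sigma_f - 1e-12
    assert 0.0 <= cb.sigma_f <= 1.0
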