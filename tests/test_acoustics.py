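"""Focused-bowl acoustic field: oracle agreement, linearity, heating law."""

import numpy as np
import pytest

from iptsl.config import AcousticParams, ScenarioConfig
from iptsl.acoustics import BowlSource, bowl_field
from iptsl.oracles import bowl_axis_pressure


@pytest.fixture(scope="module")
def tsl_config():
    return ScenarioConfig(mode="tsl")


def test_axis_field_matches_closed_form_with_hole(tsl_config):
    src = BowlSource(tsl_config, f=1.0e6)
    z = np.linspace(-0.02, 0.02, 81)
    p = src.axial_profile(z)
    ac = tsl_config.acoustic
    p_ref = bowl_axis_pressure(z + ac.focal_length, ac.focal_length, ac.outer_diameter,
                               ac.inner_diameter, src.k, ac.source_pressure)
    assert np.max(np.abs(p - p_ref)) / p_ref.max() < 0.01


def test_axis_field_matches_closed_form_full_bowl_unattenuated():
    """Full bowl (no hole), lossless medium: the classical on-axis solution."""
    ac = AcousticParams(inner_diameter=0.0, alpha_per_MHz=0.0)
    cfg = ScenarioConfig(mode="tsl", acoustic=ac)
    src = BowlSource(cfg, f=1.0e6)
    z = np.linspace(-0.03, 0.03, 121)
    p = src.axial_profile(z)
    p_ref = bowl_axis_pressure(z + ac.focal_length, ac.focal_length, ac.outer_diameter,
                               0.0, src.k, ac.source_pressure)
    assert np.max(np.abs(p - p_ref)) / p_ref.max() < 0.01


def test_linearity_in_source_amplitude(tsl_config, default_grid):
    f1 = bowl_field(tsl_config, default_grid, f=1.0e6, check_convergence=False)
    cfg2 = ScenarioConfig(mode="tsl", acoustic=AcousticParams(source_pressure=5.0e4))
    f2 = bowl_field(cfg2, default_grid, f=1.0e6, check_convergence=False)
    assert np.allclose(f2.p_amp, 2.0 * f1.p_amp, rtol=1e-10)
    assert np.allclose(f2.I, 4.0 * f1.I, rtol=1e-10)
    assert np.allclose(f2.q, 4.0 * f1.q, rtol=1e-10)


def test_heating_rate_identity(tsl_config, default_grid):
    fld = bowl_field(tsl_config, default_grid, f=1.1e6, check_convergence=False)
    rho, c = tsl_config.acoustic.density, tsl_config.acoustic.sound_speed
    assert np.allclose(fld.I, fld.p_amp**2 / (2 * rho * c))
    alpha = tsl_config.acoustic.alpha_abs(1.1e6)
    assert alpha == pytest.approx(8.55 * 1.1)
    assert np.allclose(fld.q, 2 * alpha * fld.I)
    # worked numbers: p = 1 MPa at 1.1 MHz
    I = 1e12 / (2 * rho * c)
    assert I == pytest.approx(3.226e5, rel=1e-3)
    assert 2 * alpha * I == pytest.approx(2 * 8.55 * 1.1 * 3.226e5, rel=1e-3)


def test_field_maximum_near_focus_on_axis(tsl_config, default_grid):
    fld = bowl_field(tsl_config, default_grid, f=1.0e6, check_convergence=False)
    assert abs(fld.diagnostics["max_offaxis_m"]) < 5e-4
    assert abs(fld.diagnostics["max_axial_m"]) < 2e-3


def test_focal_spot_shrinks_with_frequency(tsl_config):
    """Higher drive frequency concentrates the -6 dB focal region."""
    ax, rad = {}, {}
    for f in (0.5e6, 1.0e6, 1.5e6):
        src = BowlSource(tsl_config, f=f)
        ax[f], rad[f] = src.focal_extents_db(n=241)
    assert ax[0.5e6] > ax[1.0e6] > ax[1.5e6]
    assert rad[0.5e6] > rad[1.0e6] > rad[1.5e6]


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        BowlSource(ScenarioConfig(mode="tsl",
                                  acoustic=AcousticParams(inner_diameter=80e-3)))
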