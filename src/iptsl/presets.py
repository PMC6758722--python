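"""Named scenario presets mirroring the study's experiments.

Single-run presets return one ScenarioConfig; sweep presets return a list.
The reference tumor is R = 10 mm with a necrotic core at R/2; TSL runs use
a 100 nm carrier heated at 1 MHz unless the preset varies that parameter.
"""

from __future__ import annotations

from dataclasses import replace

from .config import ScenarioConfig, TissueParams

FREQUENCIES_HZ = (0.5e6, 0.75e6, 1.0e6, 1.25e6, 1.5e6)
TSL_DIAMETERS_M = (5e-9, 20e-9, 50e-9, 100e-9, 200e-9)
PORE_RADII_M = (50e-9, 100e-9, 200e-9)
TUMOR_RADII_M = (2e-3, 5e-3, 10e-3)


def _tsl(R=10e-3, f=1.0e6, a=100e-9, rp=None, sid="tsl"):
    cfg = ScenarioConfig(mode="tsl", tumor_radius_R=R, hifu_frequency=f,
                         tsl_diameter=a, scenario_id=sid)
    if rp is not None:
        cfg.tissue = replace(cfg.tissue, r_p=rp)
    return cfg


def preset(name: str) -> ScenarioConfig:
    """Single-run presets."""
    table = {
        "conventional_large": lambda: ScenarioConfig(scenario_id="conventional_large"),
        "large_tumor": lambda: ScenarioConfig(scenario_id="large_tumor"),
        "tsl_f1.0_a100_large": lambda: _tsl(sid="tsl_f1.0_a100_large"),
        "tsl_f0.5_a100_large": lambda: _tsl(f=0.5e6, sid="tsl_f0.5_a100_large"),
        "tsl_a5_f1.0_large": lambda: _tsl(a=5e-9, sid="tsl_a5_f1.0_large"),
        "tsl_small": lambda: _tsl(R=2e-3, sid="tsl_small"),
        "tsl_medium": lambda: _tsl(R=5e-3, sid="tsl_medium"),
    }
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(table)}")
    return table[name]()


def sweep(name: str) -> list[ScenarioConfig]:
    """Sweep presets reproducing the parametric studies."""
    if name == "sweep_frequency":
        return [_tsl(f=f, sid=f"tsl_f{f/1e6:g}_a100_large") for f in FREQUENCIES_HZ]
    if name == "sweep_tsl_size":
        return [_tsl(a=a, sid=f"tsl_a{a*1e9:g}_f1.0_large") for a in TSL_DIAMETERS_M]
    if name == "sweep_pore_size":
        return [_tsl(a=a, rp=rp, sid=f"tsl_a{a*1e9:g}_rp{rp*1e9:g}")
                for a in (20e-9, 100e-9) for rp in PORE_RADII_M]
    if name == "sweep_tumor_size":
        return [_tsl(R=R, sid=f"tsl_R{R*1e3:g}mm") for R in TUMOR_RADII_M]
    raise KeyError(f"unknown sweep preset {name!r}")
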